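"""End-to-end desk-scale pipeline glue: synthesize scenes, train, sparsify,
prune, fine-tune and evaluate with occlusion-stratified subsets.

The smoke protocol is the package's CPU-sized rendition of the full study
workflow: 64 training scenes and 16 held-out scenes at 256x256, a 10+10-epoch
two-phase transfer schedule, a 5-epoch sparsity phase (penalty 0.001,
lr 1e-4), global 65% pruning with a 50% per-layer cap, and a 30-epoch
warm-up fine-tune.  See docs/methods.md for how these sizes were chosen.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, no_grad
from .detector import build_model
from .metrics import EvalResult, MatchConfig, evaluate
from .postprocess import NmsConfig, decode_predictions, run_nms
from .sparsity_pruning import (SparsityConfig, apply_pruning,
                               build_pruning_plan, finetune, sparsity_train)
from .synth_fixtures import SceneSpec, generate_scene
from .train_sched import (CLASS_IDS, PhaseConfig, preprocess_images,
                          two_phase_train)

__all__ = ["detect_image", "evaluate_model", "make_scene_set",
           "run_smoke_pipeline", "SMOKE"]

#: Smoke-scale protocol constants.
SMOKE = {
    "n_train": 64, "n_test": 16, "size": 256,
    "phase1": dict(epochs=10, batch_size=8, initial_lr=0.05),
    "phase2": dict(epochs=10, batch_size=8, initial_lr=0.02),
    "sparsity": dict(epochs=5, batch_size=8),
    "prune_ratio": 0.65, "max_layer_prune": 0.5,
    "finetune": dict(epochs=30, batch_size=8, peak_lr=0.05),
    "score_threshold": 0.3,
}


def detect_image(model, image, score_threshold=0.3, nms: NmsConfig | None = None,
                 image_id: str = ""):
    """Forward one uint8 HWC image through the detector and post-process."""
    model.eval()
    with no_grad():
        outs = model(Tensor(preprocess_images([image])))
    dets = decode_predictions([o.data[0] for o in outs],
                              score_threshold=score_threshold, image_id=image_id)
    return run_nms(dets, nms or NmsConfig())


def evaluate_model(model, items, score_threshold=0.3, nms: NmsConfig | None = None,
                   match: MatchConfig | None = None) -> EvalResult:
    dets_by, truths_by = {}, {}
    for img, ann in items:
        dets_by[ann.image_id] = detect_image(model, img, score_threshold, nms,
                                             ann.image_id)
        truths_by[ann.image_id] = [(CLASS_IDS[o.cls], o.box) for o in ann.objects]
    return evaluate(dets_by, truths_by, cfg=match)


def make_scene_set(n: int, size: int, occlusion_range, seed: int,
                   n_larvae: int = 2, young_fraction: float = 0.5):
    """Deterministic list of rendered (image, Annotation) scenes."""
    rng = np.random.default_rng(seed)
    items = []
    for i in range(n):
        spec = SceneSpec(size=size, n_larvae=n_larvae,
                         young_fraction=young_fraction,
                         occlusion_target=float(np.round(rng.uniform(*occlusion_range), 3)),
                         lighting=("front", "side", "back")[i % 3],
                         seed=int(rng.integers(0, 2 ** 31 - 1)))
        items.append(generate_scene(spec))
    return items


def run_smoke_pipeline(seed: int = 0, stages=("train", "sparse", "prune",
                                              "finetune"), verbose=False):
    """Run the desk-scale workflow end to end; returns a result dict with the
    trained/pruned models, evaluation reports (overall and occlusion subsets
    A/B) and bookkeeping.  All randomness derives from `seed`."""
    cfg = SMOKE
    train = make_scene_set(cfg["n_train"], cfg["size"], (0.0, 0.3), seed * 7 + 1)
    test = make_scene_set(cfg["n_test"], cfg["size"], (0.0, 0.6), seed * 7 + 2)
    model = build_model("pest-smoke", seed=seed * 7 + 3)
    model.head.init_priors()
    out = {"train_items": train, "test_items": test, "history": []}

    def eval_splits(net):
        thr = cfg["score_threshold"]
        overall = evaluate_model(net, test, thr)
        a_items = [(im, an) for im, an in test if an.mean_occlusion < 0.30]
        b_items = [(im, an) for im, an in test if an.mean_occlusion >= 0.30]
        return {"overall": overall,
                "A": evaluate_model(net, a_items, thr) if a_items else None,
                "B": evaluate_model(net, b_items, thr) if b_items else None,
                "n_A": len(a_items), "n_B": len(b_items)}

    if "train" in stages:
        two_phase_train(model, train,
                        PhaseConfig(**cfg["phase1"], freeze_backbone=True),
                        PhaseConfig(**cfg["phase2"], freeze_backbone=False),
                        seed=seed * 7 + 4)
    if "sparse" in stages:
        sparsity_train(model, train, SparsityConfig(**cfg["sparsity"]),
                       seed=seed * 7 + 5)
    out["model"] = model
    out["eval_pre"] = eval_splits(model)
    if verbose:
        print("pre-prune mAP:", out["eval_pre"]["overall"].map)
    if "prune" in stages:
        plan = build_pruning_plan(model, cfg["prune_ratio"],
                                  max_layer_prune=cfg["max_layer_prune"])
        pruned = apply_pruning(model, plan)
        out["plan"] = plan
        out["pruned"] = pruned
        if "finetune" in stages:
            finetune(pruned, train, seed=seed * 7 + 6, **cfg["finetune"])
        out["eval_post"] = eval_splits(pruned)
        if verbose:
            print("post-finetune mAP:", out["eval_post"]["overall"].map)
    return out
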