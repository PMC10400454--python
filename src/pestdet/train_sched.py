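"""Training schedule: cosine-annealed learning rate, label smoothing, a
standard anchor-free detection loss with center-prior assignment, and the
two-phase transfer recipe (frozen-backbone phase, then full fine-tuning).

Defaults follow the study conditions: phase 1 trains 100 epochs at batch 32
and lr 1e-3 with the backbone frozen; phase 2 trains 100 epochs at batch 16
and lr 1e-4 with everything free; SGD momentum 0.93, weight decay 5e-4,
label smoothing 0.01.  For desk-scale smoke runs the epoch counts are scaled
down by the caller, never the formulas.
"""

from __future__ import annotations

import csv
import math
import os
from dataclasses import dataclass

import numpy as np

from . import nn
from .autograd import Tensor, maximum, minimum, softplus

__all__ = [
    "PhaseConfig", "LrSchedule", "cosine_lr", "smooth_labels",
    "assign_targets", "detection_loss", "run_training", "two_phase_train",
    "preprocess_images",
]


@dataclass(frozen=True)
class PhaseConfig:
    epochs: int = 100
    batch_size: int = 32
    initial_lr: float = 1e-3
    momentum: float = 0.93
    weight_decay: float = 5e-4
    freeze_backbone: bool = False

    def __post_init__(self):
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if not (0.0 < self.momentum < 1.0):
            raise ValueError("momentum must lie in (0, 1)")


def cosine_lr(t: int, T: int, eta: float) -> float:
    """Cosine annealing: eta_t = (1 + cos(t*pi/T)) * eta / 2 for steps t in [0, T]."""
    if T <= 0:
        raise ValueError("total steps T must be > 0")
    if not (0 <= t <= T):
        raise ValueError(f"step t={t} outside [0, {T}]")
    return 0.5 * (1.0 + math.cos(t * math.pi / T)) * eta


@dataclass
class LrSchedule:
    base_lr: float
    total_steps: int
    current_step: int = 0

    def value(self) -> float:
        return cosine_lr(self.current_step, self.total_steps, self.base_lr)

    def step(self) -> float:
        lr = self.value()
        if self.current_step < self.total_steps:
            self.current_step += 1
        return lr


def smooth_labels(one_hot: np.ndarray, eps: float = 0.01) -> np.ndarray:
    """Epsilon smoothing: positives 1 - eps + eps/K, negatives eps/K."""
    k = one_hot.shape[-1]
    return one_hot * (1.0 - eps) + eps / k


# ---------------------------------------------------------------------------
# target assignment (simplified center prior)
# ---------------------------------------------------------------------------

CLASS_IDS = {"young": 0, "old": 1}


def assign_targets(ann, input_size: int, strides=(8, 16, 32),
                   center_radius: float = 1.5):
    """Assign each ground-truth box to one pyramid level and mark positive
    cells: cells of the chosen level whose center falls inside the box and
    within `center_radius` cells of the box center.  The level is the one
    whose stride is closest (log-scale) to sqrt(area)/4, i.e. objects span
    roughly four cells.  Returns, per level, (positives, boxes, classes) with
    positives a list of (i, j, gt_index)."""
    per_level = []
    boxes, classes = [], []
    for o in ann.objects:
        boxes.append([o.box.x1, o.box.y1, o.box.x2, o.box.y2])
        classes.append(CLASS_IDS[o.cls] if isinstance(o.cls, str) else int(o.cls))
    boxes = np.asarray(boxes, dtype=np.float64).reshape(-1, 4)
    classes = np.asarray(classes, dtype=np.int64)
    level_of = []
    for b in boxes:
        ideal = math.sqrt(max((b[2] - b[0]) * (b[3] - b[1]), 1.0)) / 4.0
        level_of.append(int(np.argmin([abs(math.log(s / ideal)) for s in strides])))
    for lvl, s in enumerate(strides):
        h = w = input_size // s
        pos = []
        taken = np.full((h, w), -1, dtype=np.int64)
        for g, b in enumerate(boxes):
            if level_of[g] != lvl:
                continue
            cx, cy = (b[0] + b[2]) / 2, (b[1] + b[3]) / 2
            j0 = int(np.clip(cx / s - 0.5, 0, w - 1))
            i0 = int(np.clip(cy / s - 0.5, 0, h - 1))
            r = int(math.ceil(center_radius))
            any_cell = False
            for i in range(max(0, i0 - r), min(h, i0 + r + 1)):
                for j in range(max(0, j0 - r), min(w, j0 + r + 1)):
                    ccx, ccy = (j + 0.5) * s, (i + 0.5) * s
                    if (b[0] <= ccx <= b[2] and b[1] <= ccy <= b[3]
                            and abs(ccx - cx) <= center_radius * s
                            and abs(ccy - cy) <= center_radius * s
                            and taken[i, j] < 0):
                        taken[i, j] = g
                        pos.append((i, j, g))
                        any_cell = True
            if not any_cell and taken[i0, j0] < 0:
                taken[i0, j0] = g
                pos.append((i0, j0, g))
        per_level.append(pos)
    return {"per_level": per_level, "boxes": boxes, "classes": classes}


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------

def _gather_cells(t: Tensor, b, i, j) -> Tensor:
    """t[b, :, i, j] -> (P, C) with scatter-add backward."""
    c = t.shape[1]
    idx = (b[:, None], np.arange(c)[None, :], i[:, None], j[:, None])
    return t[idx]


def _bce_sum(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Sum of binary cross-entropies from logits: softplus(x) - x*t."""
    tt = Tensor(targets.astype(np.float32))
    return (softplus(logits) - logits * tt).sum()


def detection_loss(outputs, targets_batch, num_classes: int,
                   strides=(8, 16, 32), smoothing: float = 0.01,
                   box_weight: float = 5.0):
    """IoU box loss + objectness BCE + smoothed classification BCE.

    outputs: per-level Tensors (B, 5+C, H, W) with channels
    [dx, dy, log w, log h, obj, cls...].  targets_batch: one
    :func:`assign_targets` result per image.  Losses are summed and divided
    by the number of positives (>= 1); with no ground truth and empty
    predictions the loss is the objectness term alone.
    """
    total_pos = sum(len(t["per_level"][lvl]) for t in targets_batch
                    for lvl in range(len(strides)))
    denom = max(total_pos, 1)
    loss_box = Tensor(0.0)
    loss_cls = Tensor(0.0)
    loss_obj = Tensor(0.0)
    for lvl, s in enumerate(strides):
        out = outputs[lvl]
        bsz, ch, h, w = out.shape
        obj_t = np.zeros((bsz, 1, h, w), dtype=np.float32)
        bs, is_, js, gboxes, gcls = [], [], [], [], []
        for bi, tgt in enumerate(targets_batch):
            for (i, j, g) in tgt["per_level"][lvl]:
                obj_t[bi, 0, i, j] = 1.0
                bs.append(bi); is_.append(i); js.append(j)
                gboxes.append(tgt["boxes"][g])
                gcls.append(tgt["classes"][g])
        loss_obj = loss_obj + _bce_sum(out[:, 4:5], obj_t)
        if not bs:
            continue
        b = np.asarray(bs); i = np.asarray(is_); j = np.asarray(js)
        gb = np.asarray(gboxes, dtype=np.float32)
        pred = _gather_cells(out, b, i, j)  # (P, 5+C)
        cx = (pred[:, 0] + Tensor(j.astype(np.float32))) * float(s)
        cy = (pred[:, 1] + Tensor(i.astype(np.float32))) * float(s)
        pw = minimum(pred[:, 2], 8.0).exp() * float(s)
        ph = minimum(pred[:, 3], 8.0).exp() * float(s)
        x1, x2 = cx - pw * 0.5, cx + pw * 0.5
        y1, y2 = cy - ph * 0.5, cy + ph * 0.5
        ix = maximum(minimum(x2, gb[:, 2]) - maximum(x1, gb[:, 0]), 0.0)
        iy = maximum(minimum(y2, gb[:, 3]) - maximum(y1, gb[:, 1]), 0.0)
        inter = ix * iy
        area_g = (gb[:, 2] - gb[:, 0]) * (gb[:, 3] - gb[:, 1])
        union = pw * ph + Tensor(area_g) - inter + 1e-7
        iou = inter / union
        loss_box = loss_box + (1.0 - iou).sum()
        onehot = np.eye(num_classes, dtype=np.float32)[np.asarray(gcls)]
        loss_cls = loss_cls + _bce_sum(pred[:, 5:], smooth_labels(onehot, smoothing))
    total = (box_weight * loss_box + loss_obj + loss_cls) * (1.0 / denom)
    comps = {"box": float(loss_box.data) / denom,
             "obj": float(loss_obj.data) / denom,
             "cls": float(loss_cls.data) / denom,
             "total": float(total.data)}
    return total, comps


# ---------------------------------------------------------------------------
# training loops
# ---------------------------------------------------------------------------

def preprocess_images(images) -> np.ndarray:
    """uint8 HWC images -> float32 NCHW in [-1, 1]."""
    arr = np.stack([np.asarray(im, dtype=np.float32) for im in images])
    return ((arr / 255.0) - 0.5).transpose(0, 3, 1, 2) * 2.0


def run_training(model, items, *, epochs: int, batch_size: int, lr: float,
                 momentum: float = 0.93, weight_decay: float = 5e-4,
                 freeze_backbone: bool = False, seed: int = 0,
                 lr_fn=None, grad_hook=None, smoothing: float = 0.01,
                 history: list | None = None, phase: str = "train",
                 ckpt_dir: str | None = None):
    """Shared SGD loop.  `lr_fn(step, total_steps)` overrides the constant lr
    (defaults to cosine annealing); `grad_hook(model)` runs after backward
    and before the optimizer step (used for the L1 sparsity subgradient)."""
    if not items:
        raise ValueError("no training data")
    if epochs == 0:
        return history if history is not None else []
    size = model.config.input_size
    num_classes = model.config.num_classes
    targets = [assign_targets(ann, size) for _, ann in items]
    images = preprocess_images([img for img, _ in items])
    frozen = set(id(p) for p in model.backbone.parameters()) if freeze_backbone else set()
    params = [p for p in model.parameters() if id(p) not in frozen]
    opt = nn.SGD(params, lr, momentum=momentum, weight_decay=weight_decay)
    rng = np.random.default_rng(seed)
    n = len(items)
    steps_per_epoch = (n + batch_size - 1) // batch_size
    total_steps = epochs * steps_per_epoch
    if lr_fn is None:
        lr_fn = lambda t, T: cosine_lr(t, T, lr)
    hist = history if history is not None else []
    model.train()
    step = 0
    for epoch in range(epochs):
        order = rng.permutation(n)
        ep_loss = []
        for b0 in range(0, n, batch_size):
            idx = order[b0:b0 + batch_size]
            x = Tensor(images[idx])
            outs = model(x)
            loss, comps = detection_loss(outs, [targets[k] for k in idx],
                                         num_classes, smoothing=smoothing)
            opt.zero_grad()
            loss.backward()
            if grad_hook is not None:
                grad_hook(model)
            opt.lr = lr_fn(step, total_steps)
            opt.step()
            step += 1
            ep_loss.append(comps)
        mean = {k: float(np.mean([c[k] for c in ep_loss])) for k in ep_loss[0]}
        hist.append({"phase": phase, "epoch": epoch, "lr": opt.lr, **mean})
        if ckpt_dir:
            _save_checkpoint(model, ckpt_dir, f"{phase}_ep{epoch:03d}")
    return hist


def _save_checkpoint(model, out_dir, tag):
    os.makedirs(out_dir, exist_ok=True)
    np.savez(os.path.join(out_dir, f"ckpt_{tag}.npz"), **model.state_dict())


def write_history_csv(path, history):
    if not history:
        return
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(history[0]))
        writer.writeheader()
        writer.writerows(history)


def two_phase_train(model, items, phase1: PhaseConfig | None = None,
                    phase2: PhaseConfig | None = None, seed: int = 0,
                    out_dir: str | None = None):
    """Transfer-style schedule: phase 1 with the backbone frozen, phase 2
    training all parameters; cosine-annealed lr within each phase; label
    smoothing 0.01; optional per-epoch checkpoints under `out_dir`."""
    phase1 = phase1 or PhaseConfig(100, 32, 1e-3, freeze_backbone=True)
    phase2 = phase2 or PhaseConfig(100, 16, 1e-4, freeze_backbone=False)
    history: list = []
    for name, cfg, sd in (("phase1", phase1, seed), ("phase2", phase2, seed + 1)):
        run_training(model, items, epochs=cfg.epochs, batch_size=cfg.batch_size,
                     lr=cfg.initial_lr, momentum=cfg.momentum,
                     weight_decay=cfg.weight_decay,
                     freeze_backbone=cfg.freeze_backbone, seed=sd,
                     history=history, phase=name, ckpt_dir=out_dir)
    if out_dir:
        write_history_csv(os.path.join(out_dir, "history.csv"), history)
    return model, history
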