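# pestdet

A lightweight, anchor-free object-detection toolkit for seasonal orchard
pests — swallowtail (Papilionidae) larvae on citrus foliage — aimed at the
kind of compute that plant-protection equipment can carry.  Detection
distinguishes the two phenotypically distinct stages: **young** larvae
(instars 1–3, brown, bird-dropping mottle) and **old** larvae (instars 4–5,
green, smooth, with odoriferous horns).

The toolkit implements a complete lightweight-detector design and its
compression workflow:

* **Ghost/ECA backbone blocks** — a ghost module computes a fraction `n/s`
  of its `n` output channels with a dense convolution and synthesizes the
  rest with cheap depthwise transforms, giving a cost ratio of
  `s·c/(c+s−1) → s` over a plain convolution; a GE block wraps two ghost
  modules around efficient channel attention (ECA), whose 1-D conv kernel
  size adapts to the channel count as `k = |log₂C/γ + b/γ|_odd`.
* **TS activation** — `TS(x) = tanh(x)·softplus(x)`, used in the detection
  heads (the CBT unit) in place of SiLU (CBS).
* **ASFF** — adaptive spatial feature fusion: the three pyramid levels
  (strides 8/16/32) are resized to a common shape and blended with
  per-position softmax weights `α+β+γ = 1`.
* **Soft DIoU-NMS** — suppression that decays, rather than deletes,
  overlapping boxes: a box with `DIoU ≥ N_t` to the current best box has its
  score multiplied by `exp(−DIoU²/σ)`, which preserves detections of
  mutually occluding larvae.
* **BN-γ channel pruning** — L1-sparsity training on batch-norm scales
  (`L = L_base + λ·Σ|γ|`), global ranking of `|γ|`, ratio-quantile
  thresholding with per-layer floors and residual/depthwise coupling rules,
  structural removal with exact bias absorption, and warm-up fine-tuning.
* **Evaluation** — greedy IoU matching, precision/recall/F1, all-point
  interpolated AP (`AP = ∫₀¹ P(R) dR`), per-class AP and mAP, and
  occlusion-stratified test subsets A (mean occlusion < 30 %) and B (≥ 30 %).

Baseline YOLOX-s/m/l/x assemblies (CSPDarknet + PAFPN + decoupled heads) are
included and validated against the published parameter counts.

Because no field dataset ships with the package, a seeded **synthetic scene
generator** renders orchard-like images — foliage background, curved-capsule
larvae of both classes, leaf occluders placed to a target covered fraction,
front/side/back lighting — together with PASCAL VOC ground truth, so the
entire workflow runs end-to-end on a laptop CPU.

The neural-network layer stack (conv/BN/pooling, reverse-mode autodiff, SGD)
is implemented in-repo on numpy; convolutions use edge padding, which makes
channel pruning with bias absorption exactly function-preserving (see
`docs/methods.md`).

## Worked example

```python
from pestdet.detector import build_model, count_params
from pestdet.pipeline import make_scene_set, detect_image, evaluate_model

print(count_params(build_model("yolox-s")))   # 8968255  (8.97 M)

# render three scenes and run a (randomly initialized) pest detector
scenes = make_scene_set(3, size=256, occlusion_range=(0.0, 0.4), seed=7)
model = build_model("pest-smoke", seed=0)
dets = detect_image(model, scenes[0][0], score_threshold=0.3)
```

Training the small pest variant on 64 synthetic scenes and compressing it:

```bash
pestdet synth --out data --n-images 80 --size 256 --seed 0
pestdet train --data data --subset train --out run/train --seed 0
pestdet sparse-train --data data --weights run/train/model.npz --out run/sparse
pestdet prune --weights run/sparse/model.npz --ratio 0.65 --out run/prune
pestdet finetune --data data --weights run/prune/pruned.npz \
    --plan run/prune/plan.json --out run/ft
pestdet eval --data data --subset test --weights run/ft/finetuned.npz \
    --plan run/prune/plan.json --out run/eval
```

The same workflow is scripted in `pestdet.pipeline.run_smoke_pipeline`; a
seed-0 run on one CPU core finishes in about nine minutes and prints

```
pre-prune mAP: 0.646
post-finetune mAP: 0.790
```

— the detector learns the synthetic scenes (mAP 0.65 on 16 held-out images
before pruning), pruning at a requested global ratio of 0.65 shrinks it from
923 182 to 378 922 parameters, and the warm-up fine-tune more than recovers
the pre-pruning accuracy.  `pestdet summarize --variant yolox-s` prints the
parameter count and both FLOPs conventions (the doubled
`2HW(C_inK²+1)C_out` form and the multiply-accumulate form) for any
registered variant.

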