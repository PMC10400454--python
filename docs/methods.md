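# Methods

This note documents the models and procedures the package implements, the
choices made where the design was genuinely open, and what the synthetic
test bed does and does not establish.

## Detector architecture

The detectors are one-stage, anchor-free networks with three output levels
at strides 8/16/32; each head cell predicts `(dx, dy, log w, log h)` box
offsets, an objectness logit and per-class logits.  Two backbones share the
same neck interface:

* **CSPDarknet** (reference): Focus stem (space-to-depth slicing followed by
  a 3×3 conv), four CSP stages, spatial pyramid pooling (max-pools of
  5/9/13, a standard choice) in the deepest stage.  Depth and width
  multipliers reproduce the standard s/m/l/x family; with 80-class heads the
  learnable-parameter totals are 8 968 255 / 25 326 495 / 54 208 895 /
  99 071 455 (8.97/25.33/54.21/99.07 M), in agreement with the published
  one-decimal figures 9.0/25.3/54.2/99.1 M.
* **Ghost-GE**: the CSP stages are replaced by GE blocks (ghost module →
  optional stride-2 depthwise conv → ECA → ghost module, with a residual
  shortcut; the downsampling shortcut is a depthwise stride-2 conv plus a
  pointwise conv).  The stage plan mirrors CSPDarknet's stride schedule and
  widths so the PAFPN attaches unchanged, and SPP is retained in the deepest
  stage.  The ghost cheap transform is a 3×3 depthwise convolution, and the
  GE expansion ratio is 1 (mid = out channels); both follow the original
  ghost-module design, which describes the cheap op only as a "linear
  transformation".

The ECA kernel rule is `k = nearest odd integer to log₂(C)/γ + b/γ` with
γ=2, b=1 and ties rounded up; `k` is always ≥ 1 and non-decreasing in `C`.
ASFF compresses the two non-target levels to the target's channel count with
1×1 convs, resizes (nearest-neighbour upsampling; one stride-2 3×3 conv per
octave of downsampling), derives per-position logits with 1×1 convs and
softmax-normalizes them; it is applied to all three levels.  Heads are
decoupled (separate classification and regression towers); `head_activation`
switches every head conv unit between CBS (SiLU) and CBT (TS).  Activations
carry no parameters, so the switch leaves parameter counts unchanged.

### Complexity accounting

`count_params` sums every learnable tensor (conv kernels, biases, BN
scale/shift).  FLOPs are reported per convolution under two conventions —
`2·H·W·(C_in·K²+1)·C_out` ("paper", H×W the output size) and the
multiply-accumulate count `H·W·C_in·K²·C_out` — because published tables
for the reference family mix the two; no single convention reproduces all
printed values, so both are exposed and neither is asserted.

## Numerical stack

All layers run on an in-repo numpy tensor library with reverse-mode
autodiff (im2col convolutions, fused batch-norm and activation kernels,
-inf-padded max-pooling).  Everything is float32; gradients are verified
against central finite differences in the test suite.

**Edge padding.**  Convolutions pad spatially by edge replication rather
than zeros.  Rationale: a per-channel-constant feature map then convolves to
an exactly constant map at *every* output position, so removing a
batch-norm channel whose scale γ is zero (its output is the constant β,
hence act(β) after the activation) can be compensated exactly by a constant
shift in each consumer — into the following BN's running mean, or into the
consumer's bias.  With zero padding the compensation would be wrong in a
one-pixel border ring.  Padding mode does not affect parameter counts.
Function preservation is exact in eval mode up to float32 rounding; on the
compact networks used for verification the observed deviation is below
1e-5, while on the full detector float32 accumulation-order noise amplified
through ~40 layers reaches ~1e-3.

**Stability.**  softplus is computed as `max(x,0) + log1p(e^(−|x|))`, so
`TS(x) = tanh(x)·softplus(x)` is finite for all inputs, behaves as `x` for
large positive `x` and decays like `−e^x` for large negative `x`.

## Training schedule

Two-phase transfer recipe: phase 1 freezes the backbone (by default 100
epochs, batch 32, lr 1e-3), phase 2 trains everything (100 epochs, batch
16, lr 1e-4); SGD with momentum 0.93 and weight decay 5e-4; classification
targets use ε=0.01 label smoothing (`1−ε+ε/K` positives, `ε/K` negatives).
The learning rate follows cosine annealing `η_t = ½(1+cos(tπ/T))·η`, where
`t` is the current optimizer step and `T` the total step count — the only
reading under which the formula is a schedule.  Target assignment is a
simplified center prior: each ground-truth box goes to the pyramid level
whose stride is closest to `sqrt(area)/4`, and the positive cells are those
whose centers fall inside the box within 1.5 cells of its center (with a
single-cell fallback for tiny boxes).  The loss is
`(5·Σ(1−IoU) + BCE_obj + BCE_cls)/max(N_pos,1)` with objectness BCE over all
cells.  A full assignment with dynamic matching is out of scope; the center
prior is sufficient for the synthetic scenes and keeps training costs
CPU-sized.  Cross mini-batch normalization is implemented as standard BN.

## Sparsity and pruning

Sparsity training adds `λ·Σ|γ|` over the prunable BN scales to the loss
(implemented as the exact subgradient `λ·sign(γ)` on the γ gradients);
defaults λ=0.001, lr=1e-4, batch 16, 100 epochs, with the stated iteration
count read as epochs.  `build_pruning_plan` ranks all prunable `|γ|`
globally (stable provenance tie-break), takes the nearest-rank quantile at
the requested ratio as the threshold γ*, and prunes channels with
`|γ| < γ*` subject to:

* a per-layer floor — every layer keeps at least its largest-|γ| channel;
* coupling groups — channels tied by identity/downsample shortcuts,
  depthwise convolutions (ghost cheap branches, GE downsampling), and ASFF
  sums are pruned only if prunable in every coupled layer (union-find over
  channel slots; a group touching a fixed interface is pinned);
* an optional per-layer prune-fraction cap (`max_layer_prune`, default 1.0
  = off).  The cap exists because a global quantile over weakly separated
  scale factors — which is what short CPU-scale runs produce, since the
  per-step L1 shrink λ·lr moves γ by only ~1e-4 over a few hundred steps —
  can hollow individual layers down to the floor and destroy the network
  irrecoverably; capping trades some global ratio for per-layer capacity.

The stem convolution and the head prediction convolutions are never pruned
(fixed interfaces).  `apply_pruning` deep-copies the network and slices
weights structurally, absorbing each removed channel's constant act(β) into
the consumers as described above; re-planning with the first plan's absolute
threshold prunes nothing further (idempotence in the threshold sense — a
ratio re-applied to an already-pruned net would by construction remove
more).  Fine-tuning uses a linear warm-up (10 % of steps) to the peak lr
followed by cosine decay.

## Data tooling

VOC XML is read and written with 1-based inclusive pixel corners mapped to
continuous 0-based corners by subtracting 1 (so `xmin=1 → 0.0` and box
width = `xmax − xmin`); a non-standard `<occlusion>` element carries the
per-object occlusion fraction (absent ⇒ 0).  The offline 5× expansion draws,
per variant, one geometric op (translate, Gaussian blur, affine, rotate,
horizontal flip, or a 2×2 mosaic "splice") followed by the photometric
transform `x̃ = x·ω + ψ` (clipped to [0,255], rounded half-up); sampling
ranges ω ∈ [0.6, 1.4], ψ ∈ [−30, 30] are configurable since no canonical
values exist.  Boxes are mapped through the corner hull of the geometric
transform, clipped, and dropped when degenerate.  Splits are seeded 7:2:1
with test images stratified into subsets A/B by per-image mean object
occlusion at a 30 % cut (per-image mean rather than per-object, the simpler
of the two plausible conventions).

## Synthetic scenes

`synth_fixtures` renders deterministic orchard-like scenes: a noisy foliage
background with elliptical leaf blobs; larvae as quadratic-Bézier capsule
sweeps (young: brown with multiplicative mottle; old: green, smooth, with
two orange horn protrusions at the head); leaf-shaped occluders drawn over
each larva until its covered pixel fraction is near the target (recorded
occlusion is the exact rasterized fraction, audited in tests to ±0.05);
global lighting transforms (side: horizontal gain ramp; back: dimmed and
desaturated).  Boxes are the mask extents of the *unoccluded* larva.

What this emulates: two visually distinct classes on a cluttered background,
controllable occlusion spanning the A/B split, lighting variation, exact
ground truth.  What it does not: photographic texture, scale statistics of
field imagery, motion blur, inter-larva occlusion, label noise.  Passing
tests therefore demonstrate that the algorithms are implemented correctly
and that the pipeline can learn and survive compression on data with these
factors — not field-level accuracy.

## Desk-scale pipeline sizes

The end-to-end run (`pipeline.run_smoke_pipeline`) uses the smallest useful
rendition of the study conditions: the `pest-smoke` variant (ghost-GE
backbone, ASFF, TS heads, width multiplier 0.125, two classes, 256² input;
0.92 M parameters), 64 training and 16 held-out scenes, two-phase training
scaled to 10+10 epochs at batch 8 with lrs 0.05/0.02 (scratch-scale values;
the full-scale defaults assume pretrained weights), a 5-epoch sparsity
phase with the λ=0.001 / lr=1e-4 study values, pruning at the study ratio
0.65 with `max_layer_prune=0.5`, and a 30-epoch warm-up fine-tune — chosen
as the point where the fine-tuned pruned model reliably recovers the
pre-pruning accuracy on held-out scenes.  A seed-0 run gives pre-prune mAP
0.646 and post-fine-tune mAP 0.790 at a 923 182 → 378 922 parameter
reduction.

## Known limitations

* Pruning support covers the block types the detectors are assembled from;
  arbitrary user graphs would need their dataflow added to the
  tie/apply walkers.
* ECA layers keep their 1-D kernel size after pruning even though the
  channel count changed, and the constant-channel absorption through an ECA
  gate or an ASFF blend is approximate (both are followed by fine-tuning in
  the workflow).
* The evaluation is detection-only (no mAP@[.5:.95], no calibration).
* Checkpoints are numpy `.npz` archives, not a portable exchange format.
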