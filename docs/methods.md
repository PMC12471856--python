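# Methods

This note documents the models and procedures implemented in `hirdnet`, the
parameters that matter, the numerical choices behind them, and what the
synthetic-data experiments do and do not demonstrate.

## Enhancement pipeline

The pipeline assumes an 8-bit RGB fundus photograph with a dark, non-retinal
border.  Stages run strictly in the order crop → CLAHE → D-DoG → fusion →
resize; resizing last preserves lesion-scale detail through the enhancement
stages.

**Field-of-view crop.**  The luminosity grayscale (Rec. 601 weights
0.299/0.587/0.114) is thresholded at `background_threshold` (default 10, on
the 0–255 scale); the output is the tight bounding box of the largest
8-connected foreground component, ties broken in row-major order, no margin
added.  An image with no foreground raises an "empty fundus" error naming the
source, since every later stage assumes a retina is present.

**CLAHE.**  Contrast-limited adaptive histogram equalization with an 8×8 tile
grid and clip limit 4.0.  The clip limit follows the common convention of a
multiple of the uniform per-tile histogram level (the implementation maps it
to the tile-fraction convention of the underlying equalizer as `clip/256`).
By default the Lab lightness channel is equalized and chroma kept, so vessel
and lesion hue survives; `clahe_per_channel=True` equalizes R, G, B
independently instead.  Two behaviours worth knowing: intensities are min-max
rescaled before tile equalization, so output levels are anchored to the
image's own range; and a perfectly constant channel is returned unchanged
(a flat histogram is a fixed point of equalization, and the degenerate
rescale is numerically unstable otherwise).

**Dilated difference of Gaussians.**  The band-pass mask is
`dilate(clamp₀(gray − G_σ∗gray))` with a sampled, normalized 9×9 Gaussian
(σ = 2.0, reflected borders) applied separably, saturating subtraction (the
mask stays a valid 8-bit image; negative band-pass response carries no
additive information here), and a 2×2 grayscale dilation anchored at the
top-left pixel with edge-replicated borders, run `dilation_iterations` times
(default 1).  The 9-pixel kernel matches the spatial scale of microaneurysms
and small hemorrhages at typical fundus resolutions.

**Fusion and resize.**  The mask is replicated across the three channels and
added with saturation at 255 — fusion can only brighten, never darken, which
is asserted as a pipeline invariant.  The final bicubic (4×4 neighbourhood)
resize produces the square network input (default 224); bicubic at identical
geometry is an exact identity on grid points.

## Dataset handling

Grades follow the five-level scale 0–4.  Augmentation applies 90° and 270°
rotations (counter-clockwise) and horizontal/vertical flips — the four
orientation transforms that leave lesion appearance intact — so a targeted
class grows exactly (k+1)-fold with k transforms and the original kept.  Two
stock policies exist: all classes (balanced-corpus regime) and
Mild/Severe/Proliferative only (minority oversampling for strongly imbalanced
corpora).  Binary screening restructuring maps grade 0 → Normal and grades
1–4 → Abnormal.

Splitting is stratified by class with fractions 0.70/0.10/0.20: per class,
test and validation sizes are `round(fraction × n)` with round-half-away-from-
zero and the remainder goes to training, so class proportions are preserved
exactly and the partition is a disjoint cover.  Splits are deterministic per
seed.  Augmentation-then-split is the default order; note that it lets
transformed copies of one source image land in different folds, so figures
derived this way measure memorization-friendly generalization.  Split first
if that leakage matters for your question.

## HIRD-Net

The network is assembled from four block families.  All convolutions are
stride-1 "same"-padded unless stated; every convolution–batch-norm pair is
followed by Hard-Swish except where noted.

* **HFF stem** (224×224×3 → 28×28×128): eleven 32-filter convolutions wired
  in three fusion levels.  Level 1: 3×3 ∥ 5×5 on the input, concatenated and
  2×2/2 max-pooled (112×112×64), fused with a stride-2 5×5 on the input
  (112×112×96).  Level 2 repeats the motif on that tensor (56×56×96) and
  fuses a stride-4 7×7 taken directly from the input (56×56×128).  Level 3
  repeats once more with a stride-2 5×5 and stride-2 7×7 (28×28×128).  The
  stem widths are fully determined by the fused channel counts; only the
  kernel/stride plan is a design choice.
* **SECA attention**: squeeze (global average pool) → FC to C/r + ReLU → FC
  to C + sigmoid → channel-wise rescaling.  r = 8 everywhere; the gate lies
  strictly in (0,1), so attention only attenuates.
* **Inception block** (→ 480 channels): 1×1(128) ∥ 1×1(128)→3×3(192) ∥
  1×1(32)→5×5(96) ∥ 3×3-maxpool→1×1(64), concatenated.
* **Residual block** (→ 256 channels): three bottleneck units
  1×1(128) → 3×3(64) → 1×1(256) with additive shortcuts; the first unit
  projects the shortcut with a 1×1 (plain Conv-BN, no activation) because the
  widths differ, later units use identity shortcuts.  The leading-1×1 width
  is the one block parameter the shape plan does not pin down; 128 (half the
  block width) puts the total network at 4.92 M trainable parameters, within
  the intended ~4.8 M budget, whereas narrowing it to 64 would drop the
  model to 4.57 M.
* **Dense block** (480 → 864 channels): six pre-activation units
  BN → Hard-Swish → 1×1(256) → BN → Hard-Swish → 3×3(64); each unit consumes
  the concatenation of the block input and all previous unit outputs
  (growth 64).

Wiring: stem → SECA → [GAP₁ 128] and inception(480) → RCB(256) → 2×2 pool →
SECA → [GAP₂ 256] and inception(480) → RCB(256) → 2×2 pool → SECA →
[GAP₃ 256] and inception(480) → DCB(864) → SECA → [GAP₄ 864].  Each SECA
output feeds both its GAP descriptor and the next block.  The concatenated
1504-wide descriptor passes dropout (rate 0.2) into a dense softmax head.
Every printed intermediate shape is asserted by a construction test.

`width_multiplier` scales every channel width (subject to r dividing the
attention widths), producing topologically identical tiny models; the input
side may be any multiple of 16 ≥ 32 because the stem/pool arithmetic stays
consistent and global average pooling absorbs the rest.

**Initialization and normalization.**  He-uniform weights, zero biases,
seeded.  Batch norm uses momentum 0.99 and ε = 1e-3; its running statistics
are exponential moving averages with bias correction (dividing by
1 − momentum^t, as in Adam).  Without the correction, evaluation-mode
statistics remain ~13% biased toward their initialization after 200 steps at
this momentum, which visibly depresses short-run validation accuracy; the
correction changes nothing asymptotically.

## Objectives and training

Hard-Swish is x·ReLU6(x+3)/6; its backward pass uses the exact piecewise
derivative.  Its largest deviation from the smooth Swish gate x·σ(x) is
3σ(−3) ≈ 0.1423 at x = −3 (asserted in the tests).

The focal loss clips probabilities to [1e-7, 1] before the logarithm.  α ≥ 0
(default 2, the canonical setting) down-weights well-classified samples;
β_j > 0 balances class contributions, defaulting to inverse class frequency
N/(C·n_j) normalized to mean 1 and computed from the training split
("auto"); uniform and explicit vectors are accepted.  With α = 0 and uniform
β the loss is exactly categorical cross-entropy, which the tests use as an
oracle.

Training is mini-batch AdamW (decoupled weight decay; defaults lr 1e-3,
decay 1e-4, batch 32, 90 epochs — the short synthetic studies override batch
size and cap total steps) with per-epoch validation and best-validation-
accuracy checkpointing (ties keep the earlier epoch; the best state is
restored into the model on return).  A cosine learning-rate schedule exists
but is off by default.  Non-finite loss aborts with a diagnostic; a training
split missing a class warns.  Shuffling, dropout and initialization all
derive from explicit seeds, so identical configurations produce identical
logs.

## Grad-CAM

For target class c, the gradient of the pre-softmax score w.r.t. the dense
block's output (the 864-channel tensor feeding GAP₄, taken before the final
SECA recalibration) is spatially averaged into channel weights α_k^c; the map
is ReLU(Σ_k α_k^c FM^k), min-max normalized to [0,1] per image (a constant
raw map becomes all zeros), and bicubically upsampled to the input
resolution.  The default target class is the model's own prediction.  At a
224 input this layer is 7×7, so maps localize to roughly 32-pixel cells.

## Synthetic data

`generate_image(grade, seed, size)` draws a near-black border (intensity < 10,
so the crop always finds the retina), a circular orange disk of radius
0.45·size with a radial illumination falloff and mild noise, `vessel_count`
dark random-walk strokes, and — for grade g — 3g bright "exudate" dots and 4g
dark-red "hemorrhage" blobs inside 0.8 of the disk radius.  Lesion candidates
are drawn once per (seed, size) and a grade uses a prefix of them, so lesion
masks nest and the burden is monotone in grade by construction; output is
byte-deterministic per (grade, seed, size).

What it emulates: the gross geometry the pipeline depends on (croppable
border, bright disk, curvilinear vessels, grade-monotone lesion burden).
What it does not: real lesion morphology and texture, illumination artifacts,
camera variation, label noise, or inter-grade ambiguity.  Consequently the
synthetic experiments validate the *mechanics* — shapes, gradients,
optimization, bookkeeping, explanation plumbing — not clinical performance;
a model that overfits 40 synthetic images says nothing about grading real
fundus photographs.

## Problem sizes of the bundled studies

The overfit smoke study trains a quarter-width model on 40 synthetic images
(8 per grade, generated at 64 px, enhanced to a 48 px input) for at most 200
AdamW steps at batch 8: it reaches 100% training accuracy for every seed
tried, in under a minute on one CPU.  48 px is the smallest input at which
the resized lesions stay separable enough for the overfit to be
seed-robust.  The Grad-CAM locality study trains a screening model on ten
96-px image pairs sharing identical backgrounds (lesions are the only class
signal) for 120 steps, then checks that the class-1 activation map averages
hotter inside the lesion masks than outside.

## Known limitations

* CLAHE semantics follow the tile-equalizer described above, including its
  min-max intensity anchoring; other implementations differ in degenerate
  cases and exact clip bookkeeping.
* The numpy engine is single-threaded and eager; full-size (224 px) training
  is feasible but slow, and the package is not intended for GPU-scale runs.
* Augment-then-split (the default) leaks transformed copies across folds by
  design; see the dataset section.
* The residual block's leading-1×1 width and parts of the stem kernel plan
  are reconstructions constrained by the pinned shapes and the parameter
  budget, not uniquely determined facts.
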