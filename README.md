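# hirdnet

Diabetic retinopathy (DR) is graded from colour fundus photographs on a
five-level scale — Normal, Mild, Moderate, Severe, Proliferative — by looking
for microaneurysms (small red dots), hemorrhages (dark-red blood spots) and
exudates (bright lipid deposits).  `hirdnet` is a toolkit for building and
studying a complete CNN-based grading pipeline on such images: contrast
enhancement, class-balancing augmentation, a compact attention CNN, focal-loss
training, confusion-matrix scoring and gradient-based visual explanations.
It is aimed at researchers who want every stage of such a pipeline as
inspectable, tested library code that runs on a single CPU, with a synthetic
fundus generator standing in for clinical data.

## What is inside

**Enhancement (CLAHE-D-DoG).**  A fundus photo is cropped to the field of view
(pixels below intensity 10 are background; the largest connected bright region
is the retina), contrast-equalized with CLAHE (clip limit 4.0, 8×8 tile grid,
applied to the Lab lightness channel), and sharpened with a *dilated
difference-of-Gaussians*: the grayscale minus its 9×9, σ = 2 Gaussian blur,
clamped at zero and dilated with a 2×2 element.  The mask is replicated across
RGB and added (saturating at 255) to the CLAHE image, then the result is
bicubically resized to 224×224.

**HIRD-Net.**  A ~4.9 M-parameter CNN: a hierarchical feature-fusion stem
(eleven 3×3/5×5/7×7 convolutions concatenated across three depth levels,
224×224×3 → 28×28×128), then three multi-scale inception blocks (480 channels),
two residual bottleneck blocks (256 channels) and a six-unit dense block
(864 channels).  Squeeze-and-excitation channel attention (reduction r = 8)
recalibrates the features at four depths; a global-average-pooling descriptor
is taken at each depth and the four are concatenated (128+256+256+864 = 1504)
into a dropout-regularized softmax head.  Hard-Swish, x·ReLU6(x+3)/6, follows
every convolution–batch-norm pair.

**Objectives.**  Multi-class focal loss
`L = -(1/N) Σ_i Σ_j β_j (1-f_j(x_i))^α y_ij log f_j(x_i)` with focusing
parameter α (default 2) and per-class weights β_j (default: inverse class
frequency, normalized to mean 1), trained with AdamW and best-validation
checkpointing.  The network and its training run on a small numpy
reverse-mode autodiff engine (`hirdnet.nn`) — no GPU framework required.

**Metrics.**  Per-class precision/recall/F1 from the confusion matrix, plus
support-weighted and macro aggregates, overall accuracy, and
sensitivity/specificity for binary screening (Normal vs Abnormal).

**Explanations.**  Grad-CAM: per-channel weights α_k^c = spatial mean of
∂y^c/∂FM^k at the dense block's output, map = ReLU(Σ_k α_k^c FM^k), min-max
normalized and bicubically upsampled; optional colour overlay.

**Synthetic data.**  A deterministic generator of fundus-like images (dark
border, orange retinal disk, vessel-like strokes, grade-dependent exudate and
hemorrhage dots with nested lesion masks) so the whole pipeline is testable
offline.

## Worked example

Scoring a published per-class count table (`examples/score_published_counts.py`):

```
         class   prec%   rec%     F1%  support
        Normal    99.9   99.4   99.67     1973
          Mild    87.9   88.6   88.27      395
      Moderate    94.9   94.7   94.81     1167
        Severe    67.3   77.6   72.08      286
 Proliferative    82.4   74.8   78.41      357

macro    prec/rec/F1 : 86.50 / 87.02 / 86.65
weighted prec/rec/F1 : 93.68 / 93.47 / 93.53
overall accuracy     : 93.47%
```

Per-class rows show how the five grades differ in difficulty — Severe is the
hardest (F1 72.08%) because its lesions overlap visually with the adjacent
grades.  The macro row averages classes equally; the weighted row follows the
class sizes, and weighted recall always equals the overall accuracy.

Other examples: `examples/enhance_fundus.py` (stage-by-stage enhancement),
`examples/train_tiny_model.py` (a quarter-width model overfits 40 synthetic
images in ≤200 steps), `examples/gradcam_demo.py` (the trained model's
activation maps concentrate on the lesions).

A thin CLI mirrors the pipeline:

```bash
hirdnet synth --out-dir data --per-class 10 --seed 0
hirdnet enhance --manifest data/manifest.csv --out-dir enhanced
hirdnet split --manifest enhanced/manifest.csv --out split.csv --seed 0
hirdnet train --manifest split.csv --run-dir run0
hirdnet describe          # per-stage shape table + parameter count
```

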