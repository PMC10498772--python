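# Methods

## Problem setting

The package targets binary segmentation of lesions that are small
relative to the image (foreground typically well under 5% of pixels),
irregular in outline, and weakly contrasted against their surroundings —
the regime of pituitary adenomas in 2-D brain-MRI slices.  Severe class
imbalance drives two core choices: the Dice loss for training, and
overlap metrics (Dice, IoU) rather than pixel accuracy for evaluation.

## Network

The model is a U-Net-style encoder–decoder with `depth` levels
(default 5).  Each level applies a *basic convolution block* (3×3
convolution → batch normalization → ReLU → DropBlock) followed by a
second feature stage, and the pair is wrapped by an additive residual
shortcut.  2×2 max-pooling halves the spatial size between encoder
levels while channel width doubles from `base_channels` (default 16, so
16→256 at depth 5).  The decoder mirrors the encoder with 2×2
stride-2 transposed convolutions, concatenation of the same-resolution
encoder features, and the same two-stage block; after concatenation the
first convolution maps the doubled channel count back to the level's
nominal width.  A 1×1 convolution plus sigmoid produces the per-pixel
lesion probability map, the same H×W as the input.  Input sizes must be
divisible by 2^(depth−1); the file-level predictor pads (reflect or
zero) and crops back exactly.

### Parallel dilated convolutional module (PDCM)

The second feature stage of every level.  Five branches over the block
input:

1. a 1×1 convolution producing `F₁`, which simultaneously maps the
   input to the module's channel width (call the result `F_in'`);
2. –4. 3×3 convolutions at dilation rates 2, 4, 6, giving single-layer
   receptive-field extents of 5, 9 and 13 pixels ((k−1)·d+1);
5. the channel attention branch.

With *previous-branch fusion* (the full model) branch *k* reads
`F_{k−1} + F_in'`, chaining small receptive fields into large ones;
without it every branch reads `F_in'` alone (an ordinary parallel
multi-dilation pyramid).  The module output is the elementwise sum
`F₁+F₂+F₃+F₄+F₅`.  Three design points were genuinely open and are
resolved as follows:

* **"+" means elementwise addition, not concatenation.**  The same
  operator is used for the branch fusion, the output sum and the
  residual shortcut (unambiguously additive), and the 1×1 branch
  explicitly exists to align channel widths, which is exactly what
  addition requires.  All branches therefore share the width
  `out_channels`.
* **Under fusion, the attention branch reads `F₄ + F_in'`**; without
  fusion it reads `F_in'` like every other branch, so that the
  "no previous branch" ablation is a clean parallel pyramid.
* **Every convolution is followed by BN + ReLU** (conv→BN→ReLU
  uniformly); the architecture description places normalization
  "throughout" without fixing per-layer positions.

Dilation rates are deliberately small ({2,4,6} rather than the
{6,12,18} of atrous-pyramid practice): for very small targets, large
rates sample a discontiguous neighborhood and hurt boundary accuracy.

### Channel attention (CAM)

Squeeze-excitation style: global average pooling → 1×1 channel-reducing
convolution (reduction ratio `cam_reduction`, default 8, clamped to ≥1
hidden channel) → ReLU → 1×1 channel-restoring convolution → sigmoid.
The resulting per-channel weights in (0,1) rescale the branch input, so
for non-negative inputs the branch can only attenuate.  This is the
minimal structure consistent with "pooling, channel convolution,
sigmoid"; the reduction ratio is exposed in `BlockConfig`.

### Residual connections

`F(x) + x` around each level's [basic conv + PDCM] pair (joint
wrapping, matching the level description "a basic convolution operation
and a PDCM, connected by residuals").  When input and output channel
counts differ — every encoder level (widths double) and every decoder
level (concatenated skip halves) — the shortcut passes through a
bias-free 1×1 projection convolution with no normalization.  The
parameter cost of the projections is computed analytically by
`expected_projection_params` and asserted against built models.

### DropBlock

Structured regularization applied after each basic convolution block in
training mode only: seed positions drawn so the expected dropped
fraction equals `dropblock_rate` (default 0.1, following the training
protocol's dropout rate — DropBlock is the only dropout-like mechanism
in the architecture), expanded to `dropblock_size`² blocks (default 5,
a common choice; the size is clamped to the feature-map extent at deep
levels), with the survivors rescaled to preserve the expected sum.

## Loss and metrics

Training minimizes the soft Dice loss per image,
`1 − (2Σyᵢŷᵢ + ε) / (Σyᵢ² + Σŷᵢ² + ε)`, averaged over the batch.
Per-image averaging (rather than pooling all pixels) prevents large
lesions from dominating the gradient.  The smoothing constant ε
(default 1e-6) keeps the ratio defined on lesion-free images; ε=0
recovers the exact closed form used in the unit tests (loss 0 for
identical masks, 1 for disjoint non-empty masks, 1/3 for the
half-overlap 2×2 example with uniform 0.5 predictions, and exactly
1 − Dice for binary predictions).

Evaluation binarizes the probability map at threshold 0.5 (the
convention adopted here; nothing in the method fixes it) and computes
Sensitivity, Specificity, Dice and IoU from per-pixel confusion counts,
*exactly as defined* — including Sensitivity = TP/(TP+FP), which
conventionally is precision, not recall.  The definition is kept so
that reported numbers mean what their definition says; the conventional
TP/(TP+FN) is available via `standard=True` (`--standard-sensitivity`
on the CLI).  Degenerate denominators (e.g. an empty ground truth with
an empty prediction) return 1.0 — agreement on emptiness — with a
runtime warning.  `evaluate` reports both per-image means and
pooled-count metrics, which differ whenever confusion proportions vary
across images.

## Training protocol

Defaults follow the reference protocol for this architecture: Adam with
learning rate 1e-5, β₂ = 0.999 (the protocol's "momentum 0.999" read as
the second-moment decay, with the standard β₁ = 0.9), batch size 16,
300 epochs, 3×3 kernels, DropBlock rate 0.1.  Validation loss is
computed every epoch and weights are persisted exactly when it reaches
a new strict minimum, so the retained checkpoint is the argmin of the
dip-then-rise validation curve, not the last epoch.  Early stopping is
available (`patience`) but off by default.  No data augmentation.
Checkpoints are `.npz` weight archives with a JSON sidecar manifest
recording the full `ModelConfig`, so they are self-describing.

The desk-scale experiments in the tests and the acceptance script use
deliberately reduced problem sizes chosen as this package's own
demonstration scale: depth 3, base width 8, 64×64 phantoms, learning
rate 1e-3 for the 8-image overfit probe (≤300 full-batch steps) and a
12/4/4 split trained for 60 epochs in the pipeline run.  The 3:1:1
split ratio mirrors the motivating study design at reduced scale.

## Synthetic phantoms

`generate_phantom` emulates the data regime, not MRI physics: an
elliptical "head" with smooth low-frequency Gaussian-filtered texture
on a dark background; one star-convex lesion whose boundary radius is
perturbed by random low-order Fourier modes (amplitude = the
`irregularity` parameter, default 0.4); lesion intensity a small
additive offset (`contrast_delta`, default 0.12) over the local
texture; i.i.d. Gaussian pixel noise (`noise_sigma`, default 0.05);
area rejection-sampled into `lesion_area_fraction_range` (default
0.5–3% of the image).  Every pair is a pure function of
`(seed, index)`; splits draw from disjoint index streams; images are
quantized to 8 bits at generation so written PNGs round-trip exactly.

What passing tests on phantoms do and do not show: they verify that the
architecture, loss, optimization and evaluation machinery are wired
correctly and can learn small low-contrast irregular targets under
class imbalance.  They do not establish clinical performance — the
phantoms have no anatomy, no bias fields or acquisition artifacts, no
inter-slice correlation, exactly one lesion per image, and a contrast
model far simpler than tissue.

## Numerical core

No deep-learning framework is used: the package carries a small
reverse-mode autodiff engine on numpy arrays (`pdcnet.autodiff`) with
exactly the operators the network needs — dilated 2-D convolution
(computed as one matrix product per kernel tap in a channel-first
layout), 2×2 transposed convolution, 2×2 max-pooling with
argmax-routed gradients, batch normalization (batch statistics in
training, running buffers in evaluation, momentum 0.1, eps 1e-5), ReLU,
a numerically stable sigmoid, channel concatenation, and the reductions
of the Dice loss.  Every backward pass is hand-derived and verified
against central finite differences in the test suite.  All computation
is deterministic given seeds — parameters initialize He-normal from a
per-model `numpy` generator, data shuffling and DropBlock draw from
their own seeded generators — so phantoms, initializations, forwards
and full training runs are bit-reproducible; there are no
nondeterministic kernels to disable.  Float32 is used for training
speed; metric computations are float64.

## Known limitations

* 2-D single-channel only; no volumetric variant or multi-modal fusion.
* Binary segmentation only; no multi-class metrics or surface-distance
  measures (Hausdorff, ASSD).
* The numpy engine is single-threaded-friendly but far slower than a
  GPU framework; paper-scale training (thousands of 256×256 slices,
  300 epochs) is out of its intended range.
* Max-pooling ties route the gradient to the first maximum
  (`argmax` convention).
* The comparison suite against third-party architectures (U-Net,
  SegNet, DeepLab, ...) is out of scope; only the internal ablation
  lattice is provided.
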