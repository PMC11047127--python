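# Methods

## The model

`afmsnet` implements a 3-D encoder–decoder segmentation network for
brain-lesion volumes with two interchangeable attention encoder units
and a refined skip path. Tensors are channel-last, `(batch, H, W, D, C)`,
with 0-based voxel indices.

**SAEB (single adaptive encoder block).** A squeeze-and-excitation style
unit: 3×3×3 convolution → batch normalization → global average pooling
(the per-channel global summary S) → a 1×1×1 reduction convolution
(ratio r, default 4) with an intermediate ReLU → a 1×1×1 restoring
convolution → **softmax** over channels → channel-wise rescaling of the
batch-normalized map → ReLU. The softmax — a probability distribution
over channels rather than the canonical SE sigmoid — is a defining
property of this block and is implemented exactly as such; the test
suite asserts Σ_c A_c = 1 to 1e-6.

**DAEB (dual adaptive encoder block).** A 3×3×3 convolution produces an
intermediate tensor T; two attention branches act on T in parallel:

* channel attention: GAP → 1×1×1 reduce (ratio r, ReLU) → 1×1×1
  restore → sigmoid, giving CA ∈ [0,1]^C; T_CA = T · CA;
* spatial attention: channel-wise max-pool and average-pool maps
  concatenated to an (H,W,D,2) field → a K×K×K convolution (default
  K = 7, the standard choice for two-channel pooled-map spatial
  attention; configurable) → sigmoid, giving SA ∈ [0,1]; T_SA = T · SA.

The block output is the elementwise **sum** T_CA + T_SA: the rescaled
tensors are fused, not the attention maps; concatenation was rejected
because it would double the channel count against the decoder contract.
DAEB carries no batch-norm stage — the block is implemented exactly as
its defining sequence of operations prescribes.

**SegPath.** Each skip tensor passes through n parallel iterations,
each computing ReLU(BN(conv1×1×1(x))) + ReLU(BN(conv3×3×3(x))); the n
iteration outputs are accumulated by elementwise addition. Iterations
have separate weights and all read the module input x (parallel
accumulation); chaining iteration i into i+1 is a plausible alternative
reading and is deliberately not implemented. n = 0 degenerates to a
plain skip. Defaults per skip level are [4, 3, 2, 1] from shallowest to
deepest: shallow skips carry the largest encoder–decoder semantic gap,
mirroring residual-path practice. SegPath is applied to skips only, not
to the bottleneck.

**Assembly.** n_stages encoder blocks (default 4, widths 16·2^s), each
followed by 3×3×3/stride-2 max pooling (pad 1, so even dims halve
exactly); a bottleneck block; decoder stages of kernel-2/stride-2
transpose convolution, concatenation with the SegPath-refined skip, and
two 3×3×3 conv+BN+ReLU refinements; a 1×1×1 head to K classes with a
per-voxel softmax. Input spatial dims must be divisible by 2^n_stages.
All convolutions use same (zero) padding, so spatial dims are conserved
and borders see zero context. Initialization is He-uniform for kernels,
zeros for biases, γ=1/β=0 for batch norm, all drawn from a single
seeded generator — two builds from the same seed are bit-identical.

**Numerical backbone.** The network runs on an in-package reverse-mode
automatic-differentiation core over NumPy (float32), with 3-D
convolution via im2col and matrix multiplication. Batch normalization
uses batch statistics in training mode (eps 1e-5) and exponential
running statistics (momentum 0.9) at inference. Gradients of every
custom operator are verified against central finite differences in the
test suite, and each block's forward pass against an independent
float64 nested-loop scalar implementation (tolerance 1e-4; observed
deviations are at float32 rounding level, ~1e-6).

## Loss

Training minimizes the sum of a weighted soft Dice loss

    L_dice = 1 − (2 Σ_c Σ_i w_c G_ci P_ci + ε) / (Σ_c Σ_i w_c G_ci + Σ_c Σ_i w_c P_ci + ε)

and a categorical focal loss

    L_focal = − Σ_c Σ_i G_ci log(P_ci) (1 − P_ci)^γ.

Defaults: equal class weights (background included), ε = 1e-5 (the
stabilizer's exact value is a free choice), γ = 1. The focal term is a
sum over voxels as defined; a mean-over-voxels switch exists
(`focal_reduction="mean"`) for scale-matched experimentation.
Probabilities are clipped to [1e-7, 1−1e-7] before the logarithm so the
loss and its gradient stay finite at hard predictions; gradients pass
through unchanged inside the clip range. Losses are defined per volume;
batches are reduced by averaging per-volume losses.

## Metrics

Probability maps are binarized at 0.5, with a tie at exactly 0.5
counted positive (an inclusive threshold). Accuracy, precision, recall,
DSC and IoU come from exact voxel confusion counts. Division-by-zero
conventions: precision/recall/DSC/IoU are 1 when the denominator is
zero and both masks are empty (vacuous agreement), 0 when only one mask
is empty; degenerate cases are flagged in the report. `mean_iou` is the
unweighted mean over foreground classes/regions (background excluded).

The average Hausdorff distance is the symmetric mean of
nearest-neighbour distances between the two foreground voxel point
sets, computed with a KD-tree and scaled by voxel spacing (mm). All
foreground voxels form the point sets by default; a surface-voxel mode
is available but non-default. Empty-set conventions: both sets empty →
0 with a warning; one empty → a configurable penalty defaulting to the
mask's physical diagonal, with a warning.

Nested evaluation regions are built from raw labels {1 = NCR necrotic
core, 2 = ED edema, 4 = ET enhancing tumor}: WT = {1,2,4},
TC = {1,4}, ET = {4} — the standard convention. An alternative
tumor-core reading TC = {1,2} (core + edema) is provided as
`BRATS_REGIONS_TC_EDEMA` since both definitions circulate; the default
follows the standard one. Aggregation is reported both macro (mean ± sd
of per-case metrics) and micro (voxel-pooled confusion counts), since
either convention is defensible.

## Preprocessing

All transforms are pure functions on `VolumeRecord` (image, optional
labels, spacing, affine passthrough):

* **central_crop** — centered half-open windows `[lo, lo+target)` with
  `lo = (source − target) // 2`; an odd size difference drops the extra
  voxel from the high-index side.
* **resample** — trilinear for images, nearest-neighbour for labels;
  output voxel i samples input coordinate `i·(in−1)/(out−1)`
  (endpoint-aligned), and the recorded spacing is updated. Both
  target-spacing and target-shape modes exist because datasets are
  specified either way.
* **normalize** — per-channel z-score over the nonzero (brain) support;
  background zeros stay zero, making the transform idempotent. The
  method itself (z-score over nonzero voxels) is the standard choice
  for skull-stripped MRI with zeroed background. Constant channels are
  zeroed with a warning.
* **gaussian_smooth** — isotropic per-channel Gaussian (default σ = 0.5
  voxels); labels untouched.
* **one_hot_and_fuse** — modalities stacked on the channel axis in
  declared order; raw label 4 remapped to contiguous index 3 before
  one-hot encoding, with the inverse map applied on prediction export.
* **low_label_filter** — a volume is discarded iff its foreground
  fraction is strictly below 1 % (exactly 1 % is kept).
* **dataset_split** — seeded shuffle, floor-sized validation/test
  partitions at the configured fractions (default 80/10/10), remainder
  to training; deterministic for a fixed seed.

Every transform is label-safe: the set of distinct label values never
grows.

## Synthetic phantoms

The generator emulates the statistical structure of multi-modal
brain-lesion MRI: a ~few-percent foreground fraction, 1–3 lesions of
varying size and position, nested class shells (outer→inner defaults
(2, 1, 4) at radius fractions (1.0, 0.6, 0.3), mirroring
edema ⊃ core ⊃ enhancing-tumor nesting), multi-channel images with
per-class mean contrast (background 1.0, one intensity unit per label
step by default) and additive Gaussian noise (σ = 0.1). Axis-aligned
ellipsoids are used deliberately: the analytic volume (4/3)πabc yields
an exact oracle for expected foreground fractions, asserted to ±20 %
across seeds. Later lesions overwrite earlier labels where they
overlap. An optional "lumpy" mode warps lesions through a seeded smooth
displacement field for more organic boundaries, at the cost of the
analytic oracle (off by default).

The phantoms do **not** model MRI physics — no bias fields, partial
volume, anatomy, or scanner heterogeneity. Passing tests on phantoms
demonstrates the correctness of the blocks, losses, metrics and
pipeline plumbing and the network's capacity to fit volumetric
structure; it says nothing about segmentation accuracy on clinical
data, which additionally requires large-scale GPU training.

## Optimization

Adam at learning rate 1e-4 with weight decay 5e-4 applied as an L2
penalty on convolution kernels added to the loss (biases and batch-norm
affine parameters are exempt, the usual kernel-regularizer convention).
Batch size defaults to 1 whole volume; no patches, no augmentation, no
learning-rate schedule. Early stopping monitors validation loss
(patience 20); the best-validation checkpoint is kept and is never
worse on validation loss than the final epoch. A NaN/Inf loss aborts
with a diagnostic. Checkpoints are NumPy `.npz` archives embedding a
JSON architecture record and the label remap, so they are
self-describing.

## Problem sizes used in verification

The self-verification suite exercises tiny instances chosen so every
quantity has an exact or independent reference: blocks on ≤3³-voxel,
≤4-channel tensors against float64 scalar loops; AHD on ≤100-point sets
against an O(|P||L|) double loop; losses and confusion metrics on
two-voxel and ten-voxel hand-computable cases. The capacity benchmark
trains the miniature network (SAEB, 2 stages, base width 4, SegPath
[1,1]) on a single 32³ two-channel single-lesion phantom with Adam at
lr 1e-4 until training Dice reaches 0.95 or an epoch cap, and reports
the best training Dice; it typically crosses 0.9 within a few hundred
epochs on one CPU core. The miniature stage count (2 rather than the
default 4) is this package's choice for the benchmark: at 32³ it leaves
an 8³ bottleneck and keeps the run a single-core job.

## Known limitations

* Single-threaded NumPy execution: practical for block verification and
  miniature benchmarks, not for training at clinical scale (128³–160³,
  thousands of volumes).
* Rigid/affine registration and skull stripping are out of scope;
  inputs are assumed co-registered and stripped.
* Batch norm with batch size 1 normalizes over spatial positions only;
  this matches the whole-volume training regime but differs from
  large-batch statistics.
* The focal sum (rather than mean) makes the loss magnitude scale with
  voxel count; Adam's per-parameter normalization absorbs the scale,
  but loss values across volume sizes are not comparable.
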