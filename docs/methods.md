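# Methods

## Model

MILDNet is an encoder/decoder segmentation network for 2-D images with
binary masks. The skeleton is a U-Net of `depth` resolution stages
(default 5); stage *i* has `initial_filters · 2^i` channels (default
schedule [32, 64, 128, 256, 512]). Downsampling is 2×2 stride-2 max
pooling (`depth − 1` poolings, one skip connection per pooling);
upsampling is a 2×2 stride-2 transposed convolution that doubles the
spatial size and halves the channel count. Input spatial dimensions
must be divisible by `2^(depth−1)`; the model raises a configuration
error rather than padding silently.

Every stage is a **multi-level dilated residual (MLDR) block**: `N`
pre-activation residual levels (default `N = 2`), each computing

    y_L = h(x_L) + F(x_L, W_L),    x_{L+1} = ReLU(y_L)

with `F` = one shared BN→ReLU pre-activation feeding three parallel 3×3
convolutions at dilation rates {1, 3, 5}, fused by element-wise sum.
`h` is the identity, or a plain (not pre-activated) 1×1 projection when
the level changes the channel count. An outer identity/projection
shortcut from the block input to the last level's output, followed by a
final ReLU, makes the block residual-of-residual. The effective
receptive field of a 3×3 kernel at dilation `d` is `3 + 2(d−1)`, i.e.
{3, 7, 11} pixels for the three branches.

Each skip connection passes through a **multi-level residual (MLR)
block** before concatenation with the upsampled decoder tensor: the
same two-level residual-of-residual layout, but each level is
BN→ReLU followed by two sequential standard 3×3 convolutions, with the
channel count preserved. The decoder block then reduces the
concatenated tensor back to the stage width.

Baselines built from the same skeleton: `unet` (two 3×3 conv-BN-ReLU
units per stage, identity skips) and `residual_unet` (the same
double-conv stage wrapped in one residual shortcut, identity skips).

The head is a 1×1 convolution with bias producing logits; probabilities
are the logistic sigmoid of the logits and are reported in the open
interval (0, 1) — values are clamped away from the endpoints by 1e-12
so that saturated logits cannot yield exact 0/1 probabilities in
downstream log-scores. Convolution weights use Xavier (Glorot) uniform
initialization under a caller-supplied seed; two builds with the same
configuration and seed are bit-identical. Convolutions followed by
batch norm carry no bias (redundant parameterization).

Design choices where the block structure was genuinely open:
the fusion of the three dilated branches is element-wise sum by default
(keeps the channel count stable so the residual addition is well-typed);
concatenation + 1×1 reduction is available as `fusion="concat"`. The
residual projection on channel-changing shortcuts is a plain 1×1
convolution without its own pre-activation. Within an MLR level the two
convolutions are applied back-to-back after a single BN→ReLU, mirroring
the single pre-activation per level used in the MLDR block.

## Numerical engine

The network stack runs on `mildnet.nn`, a compact reverse-mode autodiff
engine over NumPy float64 arrays written for this package. Convolutions
use an im2col buffer and one batched GEMM per layer; "same" zero
padding at stride 1 (pad = `d(k−1)/2`), so only pooling and transposed
convolutions change resolution. Batch normalization keeps per-channel
running estimates (momentum 0.1, eps 1e-5); training mode normalizes
with batch statistics, evaluation mode with the frozen running
estimates, which makes inference deterministic. The loss is mean binary
cross-entropy computed from logits in the log-sum-exp form
`max(z,0) − zy + log(1 + e^(−|z|))` with analytic gradient
`(σ(z) − y)/n`. Every operation's vector-Jacobian product is verified
against central finite differences in the test suite. A `no_grad`
context disables graph recording for inference so large forwards do not
retain intermediate buffers.

Optimizers: SGD with momentum, Adam, RMSprop. Schedulers: step,
multi-step, cosine annealing, reduce-on-plateau and triangular cyclic.
Defaults follow the grid-search optimum of the training protocol:
Adam, learning rate 1e-3, first-moment decay 0.9 (the protocol's
"momentum 0.9" read as Adam's β₁), batch size 4, 100 epochs,
reduce-on-plateau driven by validation loss. The plateau scheduler's
internals are not specified by the protocol; factor 0.1 and patience 10
were chosen as common practice and are configurable.

## Data protocol

Images (PNG/TIFF/JPEG, grayscale or RGB) are min-max scaled to [0, 1]
per image (zero-range images map to 0) and bilinear-resized to 256×256;
masks are nearest-neighbor-resized and re-binarized at 0.5. Small
datasets are enlarged by patching *before* any resizing: the image is
reflect-padded by 16 pixels and a non-overlapping 256-pixel grid is
tiled over the padded canvas, keeping only fully contained patches — a
512×512 image yields exactly 4 patches. Images smaller than one patch
produce a single edge-padded center patch with a warning.

Splitting happens at whole-image level before patching: ids are
shuffled under the seed, `round(0.3·n)` (half-up) become the test set,
and the remainder is divided into 5 cross-validation folds whose sizes
differ by at most one (earlier folds take the remainder). The
image-level-first order matters: 165 histology images split 70/30 give
50 test images and hence 550 test patches at 11 patches per image,
which a patch-level split (30% of 1815 = 544.5) could not produce.
Plans serialize to sorted JSON, so equal seeds give byte-identical
files. Patches per image for variably-sized datasets is a free
parameter of the caller, not hard-coded.

Cross validation trains one model per round (fold *k* held out for
validation, the other four for training), restores each round's best
checkpoint by validation loss, evaluates every round's model on the one
fixed test set, and reports mean ± std per metric across rounds. The
grid-search harness enumerates the Cartesian product of candidate lists
over both training hyper-parameters (batch size, optimizer, momentum,
scheduler, learning rate) and architecture hyper-parameters (depth,
levels, dilation rates) and ranks points by mean best validation Dice,
ties broken by insertion order.

Augmentation pairs all geometric transforms between image and mask
(rotations drawn from {0, 60, 120, 180, 270} degrees — multiples of 90
applied exactly via array rotation — horizontal/vertical flips at
p = 0.5, random scaling within ±10%, shear in [−45, 45] degrees,
elastic deformation with Gaussian-smoothed displacement fields,
α = 34, σ = 4) and applies photometric transforms to the image only
(brightness/contrast/saturation/hue jitter at factor 0.2, Gaussian blur
with kernel size drawn from (3, 7), additive Gaussian noise with
variance drawn from (10, 50) on the 8-bit scale). Masks are
re-binarized after any interpolation; each non-flip transform fires
with a configurable per-transform probability (default 0.5). The
augmenter is deterministic under its seed.

## Metrics

Dice and IoU are computed by pixel counting on strictly binary masks;
predicted probability maps are binarized at threshold 0.5 at the
evaluation resolution, with no post-processing. Degenerate-input
conventions: two empty masks are perfectly similar (DC = IoU = 1,
HD = 0); one empty mask against a non-empty one scores 0 similarity and
an HD equal to the image diagonal. The Hausdorff distance ranges over
*all* foreground pixels (no boundary extraction) with the Euclidean
metric, computed via `scipy.spatial.distance.directed_hausdorff` in
both directions; tests verify it against an independent all-pairs
brute force. The training loss is the standard binary cross-entropy
with both terms negated inside the leading minus sign; the reduction is
the mean over pixels and batch. HD values are in pixel units.

Model comparison uses a paired two-sided t-test on per-fold IoU values
(paired because the same folds score both models). With zero variance
of the differences the test degenerates: p = 1 when the mean difference
is also zero, else p = 0 (a constant shift across all folds).
Significance is declared at p ≤ 0.05.

## Saliency

For each decoder stage, the gradient of the stage's mean activation
with respect to the input image is computed through the full graph,
reduced to a per-pixel magnitude by taking the maximum of |gradient|
over input channels, and bilinearly resized to the input size if
needed; the per-stage maps are averaged and max-normalized to [0, 1].
An everywhere-zero gradient yields an all-zero map rather than a
division by zero. One forward pass is run per decoder stage so gradient
accumulation between stages cannot mix.

## Synthetic data

The generator emulates five challenge regimes rather than any imaging
physics: `clean` (unions of random ellipses at configurable contrast on
a flat background, plus Gaussian pixel noise), `outliers` (clean plus
small bright specks disjoint from the mask), `obscure_boundary`
(object intensity ramped toward background along a random angular
sector, erasing part of the edge), `inconsistent_foreground` (≥ 25% of
the object textured like background), and `majority_class` (a
foreground canvas crossed by thin sinusoidal background curves,
membrane-style, foreground fraction > 0.5 by construction). Samples are
deterministic given (seed, index). Default background level 0.2 and
foreground span 0.6·contrast make a contrast-1, noise-free image
exactly two-valued, so Otsu thresholding recovers the mask — the
generator's self-check. What the regimes do **not** model: anatomical
shape statistics, texture correlations, staining/illumination physics,
annotation noise. Passing the synthetic benchmarks therefore
demonstrates that the pipeline and optimization work end-to-end, not
that clinical-grade accuracy would be reached on real data.

## Benchmark scales

All smoke benchmarks run on one CPU core. The overfit check trains the
tiny configuration (depth 3, 8 initial filters) on four clean 64×64
samples for at most 300 gradient steps, stopping early once training
Dice reaches 0.95. The end-to-end benchmark generates 64 clean images,
splits them 70/30 (19 test), trains tiny MILDNet and tiny U-Net for 15
epochs each over 3 seeds and compares median test Dice; it runs at
64×64 resolution, the package's chosen benchmark scale for single-core
execution. The outlier-regime run reports the false-positive pixel rate
outside the true mask as a regression-tracked quantity only — no
absolute claim is attached to it.

## Known limitations

- Single-class (binary) segmentation only; no multi-class head.
- 2-D only; no 3-D convolutions, no depthwise/separable variants,
  no attention.
- The NumPy engine is CPU-bound and favours clarity over throughput;
  realistic-scale training (depth 5, 256×256, thousands of images) is
  out of its intended range.
- DICOM/NIfTI readers, stain normalization and patient-level metadata
  are out of scope.
- The reference protocol's per-fold size tables for some datasets are mutually
  inconsistent; this implementation uses equal-as-possible folds.
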