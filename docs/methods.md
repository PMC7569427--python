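# Methods

## Problem and model

Retinal vessel segmentation is per-pixel binary classification of fundus
photographs: vessels are thin, branching, low-contrast dark structures on
a bright, vignetted disc, and vessel pixels are a small minority of the
image. `wanet` implements a wide-activation residual encoder–decoder
(WA-Net) for this task.

**Wide-activation residual block (WDSR-A).** An original residual block of
width c₁ spends 2·c₁²·k² weights on two k×k convolutions. The wide block
keeps the identity pathway slim at ĉ₁ channels and expands the features
*before* the ReLU by a factor r (ĉ₂ = r·ĉ₁), so more low-level feature
information survives the nonlinearity. Choosing c₁² = ĉ₁·ĉ₂ makes the two
blocks exactly parameter-matched; with the default r = 4 this gives
c₁ = 2ĉ₁, an identity the test suite checks as exact integer arithmetic.
A 1×1 convolution adapts the identity path only when input channels differ
from ĉ₁.

**LASPP bottleneck.** Four parallel 3×3 atrous convolutions with dilations
d = 2^i, i = 0..3, act on the shared bottleneck features; each is followed
by ReLU and the outputs are summed. A k×k kernel at dilation d has
receptive field Rf = (k−1)(d−1)+k, so the branches see 3, 5, 9 and 17
pixels per axis and capture vessels of mixed calibre without extra
parameters. The LASPP convolutions are weight-normalized: w = g·N/‖N‖,
which decouples the kernel's norm (‖w‖ = g exactly) from its direction and
avoids batch-statistics dependence at the bottleneck.

**Assembly.** Encoder: one input batch-norm (the only BN in the default
network), then WDSR-A blocks of slim widths (16, 32, 64), each followed by
2×2 max pooling, then LASPP with 128 channels. Decoder: three stages of
nearest-neighbour 2× upsampling + 3×3 convolution (no activation), skip
concatenation with the matching encoder features, and a WDSR-A block at
the mirrored slim width. Head: leaky ReLU (slope a = 0.3) on the decoder
output is summed with a leaky ReLU on a 1×1-conv global shortcut from the
post-BN input, followed by a 1×1 convolution to 2 channels and a per-pixel
softmax. Patch size must be divisible by 8 (three poolings).

Points the architecture description leaves open, resolved here as package
design choices: "same" zero-padding everywhere; nearest-neighbour
upsampling; decoder widths mirror the encoder; the global shortcut runs
from the post-BN input to the pre-head decoder features; skip connections
concatenate channels. Convolutions carry biases; the parameter-count
identities count kernel weights only.

**Ablation variants.** `network_1` replaces the wide blocks with
preactivated residual blocks (BN-ReLU-Conv ×2) and drops weight norm from
LASPP; `network_2` additionally sets channels to 32-64-128-256-128-64-32
(encoder 32/64/128, bottleneck 256); `network_3`/`network_4` are WA-Net
with 3 (d = 1,2,4) and 5 (d = 1,2,4,8,16) LASPP branches.

## Objective

L = L_CE + L_Dice, with binary cross-entropy on the vessel-probability
channel and the smoothed Dice loss
1 − (2Σyᵢp̂ᵢ + k)/(Σyᵢ + Σp̂ᵢ + k), k = 1.0. The Dice term counters the
vessel/background class imbalance; the smoothing makes the empty-mask case
well defined. Probabilities are clipped to [1e-7, 1−1e-7] before
logarithms. CE is defined as a sum over pixels with a mean-reduction
option; the trainer defaults to mean so the CE:Dice weighting does not
scale with patch size (the two reductions differ only by that constant).

For optimization the gradient is taken in logits space
(`segmentation_loss_logits`): the CE part becomes the bounded p − y, which
remains informative where the float32 softmax saturates to exactly 0 or 1;
a probability-space gradient is zeroed there by the clip and can stall
training from a fresh initialization. The loss *value* is identical to the
probability-space form, and the two gradients agree through the softmax
jacobian away from saturation (asserted in tests).

## Training and inference

Adam with lr 0.001, β₁ 0.9, β₂ 0.999, ε 1e-8; batch size 32; He-normal
initialization (variance 2/fan_in) of all conv kernels, with the draw
becoming the direction tensor (g = ‖N‖) under weight normalization; a
seeded 90/10 train/validation split of the patch set. Training runs a
fixed number of epochs (no early stopping); the best-validation parameters
are checkpointed on the side. The single input BN uses running statistics
(momentum 0.99) at inference.

Training patches are sampled at uniformly random fully-inside positions
(with replacement), optionally restricted to patch centres inside the
field-of-view disc; test-time inference tiles the image with the
deterministic sliding-window grid and averages overlapping vessel-
probability windows. When the stride does not divide the image, one final
edge-aligned window per axis guarantees full coverage, making
extract→reconstruct an exact identity on any image.

## Preprocessing

Grayscale conversion uses BT.601 luminance weights (0.299, 0.587, 0.114).
Standardization is a per-image z-score followed by min–max rescaling back
to [0, 1], which the subsequent bounded-range operators need; dataset-level
statistics can be supplied instead. CLAHE uses scikit-image with a tile
grid (default 8×8) and an OpenCV-convention clip limit (default 2.0,
mapped to skimage's normalized limit over 256 bins); a constant image is
returned unchanged. Gamma correction v → v^γ with γ = 1.2 darkens the
midtones, deepening vessel/background separation after equalization.

## Synthetic fundus generator

The generator emulates the features that make the task hard: recursive
bifurcating vessel trees seeded on the FOV margin, stroke width tapering
linearly from `root_width` (default 4 px) to 1 px terminals, rasterized by
disc-stamping without anti-aliasing so the ground truth is exactly binary;
a bright vignetted background disc (base 0.65, near-black outside the
FOV); vessels darkened by `vessel_darkness`·background (default 0.35, i.e.
low contrast); Gaussian edge blur (σ 0.6) and additive Gaussian sensor
noise (σ 0.03). Defaults give a vessel fraction of ~13–15 % of the FOV,
in the range of real fundus datasets and strongly class-imbalanced.
Per-image seeds derive from a master seed via `SeedSequence`, so datasets
are bit-reproducible.

What it does *not* model: tortuosity and calibre statistics of real
vasculature, the optic disc, the macula, lesions/exudates, colour, or
camera-specific noise. Passing the end-to-end tests therefore shows the
pipeline learns and generalizes on dark-branching-structure phantoms, not
that it attains published benchmark numbers on DRIVE/STARE; the CLI will
run on those datasets but no benchmark harness is included.

## Numerical engine

The network runs on a small channels-last (NHWC) CPU engine inside the
package: dilated 3×3 convolutions are direct jit-compiled kernels
(vectorizing over input channels when a layer contracts, output channels
when it expands), 1×1 convolutions are GEMMs, and the input gradient of a
stride-1 "same" convolution is computed as the "same" convolution with the
spatially flipped, channel-transposed kernel, so backward runs on the same
kernels. Gradients of every layer and of the assembled network are
verified against central finite differences in float64 (directional
derivative, rel. error < 1e-4). Parameters are float32; padded scratch
canvases are reused across same-shaped calls.

## Problem sizes used in the checks

The end-to-end acceptance run uses the scaled-down network (slim widths
8/16/32, LASPP 64) on 2,000 patches (48×48) sampled from six 160×160
phantoms, 15 epochs, batch 32, with two held-out phantoms evaluated at
stride 8 — chosen so a single-core run finishes in minutes while leaving
the architecture, loss, optimizer and patch geometry exactly as specified.
Unit and property tests use miniature networks (widths 2/4/8, patch 16)
and 96×96 phantoms. The cross-domain check trains once at the miniature
scale and evaluates on a mildly shifted generator configuration
(noise 0.03→0.045, darkness 0.35→0.30).

## Known limitations

- Default (paper-scale) widths train slowly on one CPU; the engine is
  written for desk-scale experiments, not GPU-scale benchmark training.
- `standardize(mode="per_dataset")` requires caller-supplied statistics;
  no dataset-scanning pass is provided.
- ROC points come from the full threshold sweep (`drop_intermediate`
  disabled) and can be large for big images; metrics JSON output omits
  them unless requested.
- The synthetic generator's realism limits are listed above; conclusions
  about real fundus data require real data.
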