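# Methods

## Model

The network is a two-branch, multiscale encoder with attention-gated fusion,
operating on 64×64 RGB patches (any spatial size divisible by 4 works; the
model is fully convolutional). The wiring and per-stage shapes are listed in
the README. Three design points deserve explanation:

**Attention gates.** Shuffle Attention (SA) splits channels into `G` groups
and gates half of each group by channel statistics (global average pooling →
per-channel affine → sigmoid) and the other half by spatial statistics
(per-channel normalization over spatial positions → affine → sigmoid); the
affine parameters are shared across groups, and a channel shuffle (two
interleaved blocks) follows reassembly so information crosses group
boundaries. A flag (`sa_shuffle`) disables the shuffle for ablation.
Efficient Channel Attention (ECA) gates all channels through a 1-D
convolution of the pooled descriptor; its kernel size is the odd integer
nearest to `log₂(C)/r + b/r` with ties rounded down and a floor of 1
(defaults r = 2, b = 1, giving K = 3 for the 64-channel stages this network
applies it to).

**Gate initialization.** All SA affine parameters and the ECA kernel start
at zero, so every gate begins at the neutral value σ(0) = 0.5 — a uniform
0.5 scaling that downstream batch normalization absorbs. Zero-started gates
are not dead: the gradient of a gate weight is proportional to the pooled
(nonzero) feature statistics, so the gates differentiate immediately.

**Head and loss.** The head ends in a full C_B_R unit (Conv → BN → ReLU)
with 3 output channels followed by ×2 bilinear upsampling; the loss applies
a per-channel sigmoid and binary cross-entropy against the vessel mask
replicated across channels, and inference averages the three per-channel
sigmoids. Because the logits are ReLU'd, the sigmoid output lives in
[0.5, 1): background pixels train toward logit exactly 0 (probability
exactly 0.5), and the strictly-greater-than-0.5 binarization maps them to
background. This gives the characteristic training trajectory — sensitivity
near 1 from the start, specificity climbing as background logits collapse to
zero — and a loss floor near `(1 − vessel fraction)·ln 2`, which still
decreases monotonically while vessel predictions sharpen. A two-channel
softmax head remains available through `NetworkConfig.head_filters`.

One stated stride in the source topology is internally inconsistent: the F3
path names an upsampling stride of 4 from a 16×16 map while declaring F3 as
32×32, which the fusion concat with the 32×32 maps requires. The declared
shapes win; both fusion-stage upsamplers run at factor 2
(`NetworkConfig.upsample_erratum` records this).

## Numerical core

No deep-learning framework is used. A small reverse-mode automatic
differentiation engine (`vesselfuse.autograd`) provides exactly the
operations the model needs:

- **Convolution** is evaluated as k² shifted GEMMs (one channel-mixing
  matrix multiply per kernel offset), which avoids materializing an im2col
  matrix; 1×1 convolutions collapse to a single channel GEMM. Backward
  passes reuse the same scheme.
- **BatchNorm** (training mode) uses biased batch statistics with ε = 1e-5
  and momentum 0.1 running averages for evaluation; gradients flow through
  the batch statistics. The BN → ReLU pair in every C_B_R is fused into one
  primitive with a hand-derived backward to keep one output buffer per unit.
- **Group normalization** in SA is per-channel over spatial positions
  (ε = 1e-5), also a fused primitive.
- **Upsampling** is a separable linear map: precomputed 1-D interpolation
  matrices (half-pixel-centred bilinear with edge clamping, or nearest) are
  applied along each spatial axis as large GEMMs; the backward pass is the
  transposed map. Matrices are cached per (size, factor, mode).
- The graph releases each intermediate's activation and gradient as soon as
  its backward step has run, so peak memory stays near the forward-graph
  size (≈0.5 GB at batch 32, ≈2 GB at batch 128).
- Training tensors are float32; the engine preserves float64 end to end,
  which the test suite uses for central-difference gradient checks of every
  primitive and of the fully assembled network.

Convolution weights are He-normal initialized, BN scale/shift at 1/0;
the probability clamp in the cross-entropy is 1e-7. Ties and degenerate
cases: all-constant inputs give zero group-norm statistics (gate = σ(bias));
a zero-channel-variance batch is stabilized by ε; binarization is strictly
greater-than, so an exact 0.5 is background.

## Training pipeline

Patches are sampled at seeded uniform random origins (default 500 per image;
when a field-of-view mask exists, candidates with under 50 % FOV coverage
are rejected) and augmented by flips, right-angle rotations and integer
translations in [−8, +8] px with zero fill — pure pixel permutations or
shifts, so masks stay exactly binary. The optimizer is Adam
(β = 0.9/0.999, ε = 1e-8) at an initial learning rate of 1e-3, multiplied
by 0.9 after every epoch; the published schedule is 100 epochs at batch 128.
The "exponential decay rate 0.9" is read as this per-epoch learning-rate
multiplier, not an optimizer moment coefficient, since it is stated beside
the initial learning rate. Validation runs after each epoch by grid-tiled,
overlap-averaged full-image inference (stride 32), and the weights with the
best validation accuracy are retained.

Desk-scale runs in the test suite use 20 training phantoms × 100 patches
(≈2,000 patches), 10 epochs, batch 32: with only two thousand patches,
batch 32 provides ~630 optimizer steps versus ~160 at batch 128, which is
the difference between a converged and a half-converged model at this data
volume, and it is also the fastest batch size per sample on a single CPU
core. The full-scale batch-128/100-epoch schedule remains the
`TrainConfig` default.

Metrics (accuracy, sensitivity, specificity) are computed from pixel
confusion counts inside the FOV when a FOV mask exists (`use_fov=False`
switches to whole-image counting); a metric with a zero denominator is
reported as undefined (`None`), never coerced to 0. Aggregate metrics are
micro-averages: metrics of the summed per-image counts.

## Synthetic phantoms

The generator emulates what a patch-based vessel segmenter actually sees:
curvilinear branching tubular trees, darker than a bright unevenly
illuminated background (amplitude 0.15 linear ramp in a random direction),
inside a circular field of view (radius 0.95 of the half-side), with
additive Gaussian pixel noise (σ = 0.03). Trees grow as segment random
walks (length U(10, 30) px, heading jitter ±10° per step); side branches
spawn with probability 0.35 at ±U(10°, 40°) and carry 0.8× the parent
width, stopping below 1 px. Segments render with a Gaussian cross-section
whose FWHM equals the local width (root width 5 px, 3 % taper per segment).
A fixed total centerline-length budget (1,400 px per 256² image, scaled by
area) is shared across the five root trees, which pins the expected vessel
density: the foreground fraction is 0.10 ± 0.005 (std over seeds), inside
the 0.05–0.20 band typical of fundus vessel maps.

Ground truth is the noiseless vessel response thresholded at half its unit
peak — labels are exact by construction, never derived from the noisy
image. The masks therefore have none of the inter-observer ambiguity of
manual annotations.

What the phantoms do **not** model: optic disc and macula, exudates and
hemorrhages, vessel-width-dependent contrast, central light reflex, color
(channels are replicated gray), JPEG artifacts. Passing the desk-scale
learning test demonstrates that the architecture, loss, optimization and
evaluation plumbing work end to end on curvilinear structures with exact
labels; it does not certify clinical-grade performance on real fundus
images, which requires the external benchmark workflow and the full
schedule.

## Known limitations

- CPU-only; a training epoch on 2,000 patches takes on the order of a
  minute on one core. There is no GPU path.
- BatchNorm statistics assume batches are patch-level i.i.d. samples; very
  small batches (< 8) give noisy normalization.
- The ReLU'd head cannot express probabilities below 0.5; with the strict
  threshold this is benign for binary masks but makes the probability maps
  one-sided (background mass concentrates exactly at 0.5).
- `split_dataset` encodes the benchmarks' standard divisions positionally
  on the sorted id list; ids must therefore sort in the official order.
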