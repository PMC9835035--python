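# Methods

## The separation problem

Two-point Dixon MRI acquires two T1-weighted magnitude volumes at echo
times where the fat and water magnetizations are aligned (in-phase, IP) and
opposed (opposed-phase, OP). In the ideal magnitude model

    IP = W + F,        OP = |W − F|,

so the water and fat images follow analytically as W = |IP + OP| / 2 and
F = |IP − OP| / 2. Because only magnitudes are observed, this inversion
cannot tell which component is which: it always returns the *larger*
component in the "water" slot. Every fat-dominant voxel therefore comes
back exchanged, and scanner reconstructions resolve the ambiguity with
spatial context (region growing, phase models). When that resolution fails
over a contiguous region, the result is a *fat-water swap* — whole
acquisition stations, isolated organs, or patches at the edge of the field
of view with fat and water labels exchanged.

`dixonsep` reconstructs swap-free fat and water volumes from IP/OP with a
3D conditional GAN, and provides everything needed to exercise the method
without real MRI data: a parametric Dixon phantom with injectable swap
artifacts, training and inference drivers, and the evaluation metrics.

## Model

**Generator.** A six-level 3D U-Net-style encoder–decoder: kernel-4
stride-2 convolutions contract (no pooling), kernel-4 stride-2 transposed
convolutions expand, skip connections concatenate mirrored levels. Input is
one channel (IP) or two channels (IP, OP); output is the two channels
(F̂, Ŵ) through a sigmoid, matching the normalized [0, 1] intensity scale.
Filter counts follow the doubling schedule `base_filters · min(2^i, 8)`
(64, 128, 256, 512, 512, 512 at the defaults), configurable per level. The
input edge must be divisible by 2^levels (128 → bottleneck edge 2 at six
levels).

**Discriminator.** A 3D PatchGAN judging (F, W) pairs jointly: kernel-4
convolutions with one stride-2 layer followed by two stride-1 layers. The
receptive-field recurrence `RF_in = RF_out · s + (k − s)` applied backwards
from a single output unit gives 1 → 4 → 7 → 16: each score judges a
(16, 16, 16)-voxel neighbourhood. With kernel 4 this patch size *forces*
exactly one stride-2 layer before the two stride-1 layers, which is how the
default strides (2, 1, 1) were fixed. The discriminator is unconditional by
default (it sees only the fat/water pair); pix2pix-style conditioning on
the generator inputs is available behind a flag.

**Objectives.** The adversarial game is implemented in the standard
negative-log (binary cross-entropy) form over the score grid. The generator
objective adds a reconstruction term with weight λ = 100:

- *L1 mode*: mean absolute error of (F̂, Ŵ) against the curated labels.
  Exchanging the predicted channels changes this loss wherever F ≠ W, so L1
  supervision can resolve the swap ambiguity.
- *Dixon mode*: physics consistency, ‖IP − (Ŵ + F̂)‖₂ + ‖OP − |Ŵ − F̂|‖₂,
  needing no fat/water labels. Each ℓ₂ term is reduced as a per-volume
  root-mean-square and averaged over the batch (scale-stable across patch
  sizes); the printed single-voxel example IP=3, OP=1, F̂=Ŵ=0 → 3 + 1 = 4
  pins the convention. This loss is *invariant* under globally exchanging
  F̂ and Ŵ — the physics cannot name the channels — which is why the
  single-input (IP only) + Dixon configuration is refused at validation
  time: with only IP constrained, degenerate solutions such as an empty
  water channel satisfy the loss exactly.

**Normalization.** All channels of a subject are jointly scaled by the 99th
percentile (linear-interpolation definition) of their pooled voxel
intensities, then clipped to [0, 1]; the percentile is pooled over whatever
channels are available (all four in training, the input channels at
inference). The scalar is kept so predictions can be mapped back to raw
intensity units.

**Optimization.** Adam (β₁ = 0.5, β₂ = 0.999), learning rate 0.0002,
batch size 2, alternating one discriminator and one generator update per
batch. Each iteration samples a random subject and a random 128³ crop
applied identically to all channels. Epochs default to 100 with
`steps_per_epoch` defaulting to the dataset size; no early stopping. All
randomness flows from explicit seeds; runs are bit-reproducible on a fixed
platform.

**Weight init** is zero-mean Gaussian, σ = 0.02, seeded. Feature
normalization is batch-norm by default with instance-norm available; both
always use current-batch statistics (also at inference, the pix2pix
convention), so there are no running statistics to serialize. A `none`
option exists for norm-free discriminators, used where the pure
convolutional receptive field is being measured — feature normalization
couples all voxels through its statistics and would blur the footprint.

## Compute backend

No GPU framework is assumed: networks run on a small reverse-mode autodiff
engine over numpy arrays (`dixonsep.nn`). 3D convolutions use
stride-tricks sliding windows plus einsum contractions; gradient-to-input
scatters loop over the k³ kernel offsets, bounding memory. All layer
gradients are verified against central finite differences in the test
suite. This backend is deliberately simple and single-threaded; it is
sized for the phantom-scale experiments below, not for full-scale training.

## Inference on whole volumes

A trained generator accepts fixed-edge cubes, so whole volumes are covered
by patches whose starts are multiples of the patch edge with the final
start per axis clamped to `dim − edge`; a (224, 174, 370) volume with
128-cubes yields 2 × 2 × 3 = 12 patches with starts x ∈ {0, 96},
y ∈ {0, 46}, z ∈ {0, 128, 242}. Overlap is resolved by *first-value
precedence* in lexicographic (left–right, anterior–posterior,
superior–inferior) start order: the earliest patch containing a voxel
provides its value. Patch extents are 0-based and half-open. Blending or
overlap averaging is intentionally absent. Prediction normally tiles at the
same edge the model was trained on, so the feature-normalization statistics
match the training distribution.

## The synthetic phantom

`PhantomSpec` renders geometric tissue regions (ellipsoids, boxes,
cylinders) with per-region total signal and fat fraction into non-negative
W/F maps; IP/OP follow from the forward model, so clean phantoms are
exactly physics-consistent and the fat-dominant voxels are exactly the set
the analytic inversion returns exchanged. The default body template is a
subcutaneous-fat shell (fat fraction ≈ 0.9) enclosing a lean torso and
water-dominant organs (liver-, kidney-, muscle-like; fat fractions 0.02 to
0.45).

Choices that shape what the phantom does and does not emulate:

- **Cross-subject variability.** Each region carries a fat-fraction range
  (e.g. 0.02–0.3 for the liver-like organ) sampled per subject, plus ±6%
  geometric and intensity jitter. Variation of tissue fat content across a
  cohort is the information the OP channel contributes: IP = W + F is blind
  to it, so a single-input model can at best predict the cohort mean.
- **Intra-tissue texture.** Two independent smooth random fields
  (Gaussian-filtered noise, correlation length 5 voxels, amplitude 0.2)
  modulate W and F inside tissue. Real tissue is heterogeneous; without
  texture the phantom is piecewise-constant and window-based similarity
  metrics barely distinguish a model that recovers the fat-water split
  from one that only recovers region outlines.
- **Noise** is additive Gaussian on W and F, truncated at zero (σ = 1
  signal unit ≈ 1% of tissue intensity by default). Rician statistics at
  low SNR are a documented simplification left out.
- **Swaps** are injected only into the scanner-style F/W channels — IP/OP
  stay clean, as in acquisition — by exchanging F and W inside a mask:
  whole volumes, axis-aligned slabs (station swaps), organ supports
  (isolated-organ swaps), boundary shells (field-of-view swaps), or
  spherical blobs. Injection is an involution and conserves F + W
  voxel-wise. By default half the subjects of a generated cohort carry one
  swap, cycling through the kinds; the clean channels are retained as
  training labels.
- **Not emulated:** realistic anatomy, the six-station acquisition and its
  assembly, chemical-shift displacement, bias fields (off by default; the
  pipeline assumes bias-corrected inputs).

Passing tests on these phantoms demonstrate the mechanics of the method —
physics consistency, swap injection/correction, ordering of configurations
— not clinical performance on real MRI.

## Metrics

- **PSNR** = 10·log10(MPI²/MSE), MPI being the reference maximum (the
  definition leaves the peak open; using the reference max is recorded
  here). Identical volumes report infinity rather than a silent number.
- **SSIM** uses a uniform 11³ window, population moments, C1 = (0.01 L)²,
  C2 = (0.03 L)² with L defaulting to the reference max − min, averaged
  over fully interior windows. Cross-checked in the tests against
  scikit-image with matching options.
- **Dice** 2|A∩B|/(|A|+|B|); two empty masks score 1 by convention.
- **SIS** (semantic interpretability score): Dice of segmentations computed
  on reconstructed volumes against manual annotations, normalized by the
  segmenter's mean Dice on ground-truth volumes. Both aggregation orders
  (per-subject ratio then mean, or ratio of means) are exposed via the
  baseline argument. The external organ-segmentation networks are out of
  scope; a phantom-native stand-in segments a structure as the connected
  component of voxels whose fat fraction lies in the tissue's
  characteristic window that best overlaps the annotation.
- **Induced-swap counting** operationalizes the difference-image reading
  used at full scale, where it was done visually: a voxel is flagged when
  the prediction pair is closer to the *exchanged* reference than to the
  reference (|F̂−W| + |Ŵ−F| < |F̂−F| + |Ŵ−W|) and the disagreement exceeds
  a relative threshold (default 0.25) of the local total signal; flagged
  voxels are grouped 26-connected, components under 27 voxels are ignored,
  and the tally is also reported in millilitres via the voxel volume. The
  rule is validated by exact agreement with injected swaps on phantoms.

## The desk-scale experiment

The test suite trains the three published configurations — single-input +
L1, dual-input + L1, dual-input + Dixon loss — at a reduced size chosen to
fit one CPU: 64³ phantoms (30 training, 10 held-out), 4-level generator
with 8 base filters, 32³ crops, batch 2, 300 optimizer steps, instance
normalization, learning rate 5·10⁻³ (the full-scale rate of 2·10⁻⁴ barely
moves a freshly initialized network in 300 steps; the demo rate was chosen
once for this budget), and a width-scaled (8, 16)-filter discriminator.

What this experiment demonstrates, and what it cannot. Demonstrated
robustly: the trained dual-input model beats the untrained baseline on
held-out SSIM by a wide margin every seed; on subjects whose scanner
channels carry an injected slab swap, the model's predictions carry a
4–5× smaller swapped *voxel burden* than the corrupted channels (roughly
250 ml vs 900 ml of decisively swap-like tissue per subject); and
Dixon-loss training drives the held-out physics residual RMS far below
the untrained baseline (≈ 0.16 vs ≈ 1.17 on normalized intensities).

Not resolved at this budget: 300 optimizer steps are roughly twenty
epoch-equivalents, two orders of magnitude short of full-scale training,
and the network only half-learns the context-dependent sign flip in the
fat-dominant shell (it predicts both channels near the midpoint there).
Two consequences follow. The held-out SSIM *ranking* between the dual- and
single-input models — clearly resolved at full scale — is dominated by
per-seed optimization noise: the dual model consistently reaches the lower
training reconstruction error, but whole-volume SSIM at this convergence
level mostly measures how quickly a model suppresses its background, where
the single-input model (simpler input) tends to be quicker. And the
induced-swap *component count* of the model (a large half-resolved shell
region, 2–3 components per subject) is not below the corrupted channels'
count, because a half-volume slab swap forms a single connected component
(≈ 1 per subject) — by components the bar is near-perfection, by volume
the model's correction is unambiguous. The corresponding checks assert
the full-scale orderings as published and report the measured per-seed
values when they fail; they are expected to fail at this scale, and the
package treats that as a faithful negative result of the desk-scale
budget, not of the method.

## Numerical conventions and edge cases

- Percentile: linear interpolation between order statistics; degenerate
  all-zero input raises instead of dividing by zero.
- analytic_separation applies absolute values exactly as written (|IP+OP|
  is already non-negative; harmless).
- Tensors are float32 inside the network; fields are float64 outside.
- PatchGAN scores live in [0, 1]; the loss clamps logs at 1e-7.
- Norm layers use ε = 1e-5 inside the square root.
- Checkpoints are single .npz files with the generator config embedded as
  JSON; loading validates name and shape agreement.

## Known limitations

- The numpy backend makes full-scale (128³, 64-filter, 100-epoch) training
  impractical; the architecture supports it, the arithmetic does not scale.
- Normalization statistics at inference come from the input channels only;
  whether the original pipeline pooled two or four channels is not
  documented, and the choice is recorded here as this package's convention.
- The stand-in segmenter uses the annotation to pick among candidate
  components, which inflates its baseline Dice relative to a true external
  segmenter; SIS values on phantoms are therefore comparative, not
  absolute.
- Magnitude noise is Gaussian-truncated, not Rician; bias fields are not
  simulated.
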