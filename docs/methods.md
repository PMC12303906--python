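# Methods

## Model

DualPlaqueNet is a U-Net-style encoder–decoder with two output heads over
a shared trunk. The encoder has `depth` stages (default 4; the smoke
protocol uses 3); each stage is two 3×3 convolutions with batch
normalization and ReLU, followed by a channel-attention block and 2×2 max
pooling, doubling channels from `base_channels` (default 64; tests and the
smoke protocol use 8–16). The decoder mirrors the encoder with 2×2
transposed convolutions and skip concatenations; a 1×1 convolution emits
`num_classes` score maps. The size-regression branch taps the bottleneck:
global average pooling, one hidden fully-connected layer with ReLU, and a
linear 2-output layer giving (long, short) in mm. Diameter outputs are
linear (unbounded above); the harness optionally z-scores the targets with
training-split statistics and inverts the transform at prediction time
(on, by default — it decouples the size-loss scale from the plaque size
distribution).

### Channel attention with stacked 1-D convolutions

Each attention block pools its feature map to a length-C channel
descriptor, passes it through `eca_conv_layers` successive single-channel
1-D convolutions along the channel axis (ReLU between layers, none after
the last), and maps the result through a sigmoid to weights in (0, 1) that
rescale the channels. With one layer this is exactly the original ECA; the
default of two stacked layers is the minimal "multi-layer" reading and is
configurable. Kernel size is either explicit (odd) or adaptive,
`k = |log2(C)/2 + 1/2|` truncated to an odd integer and clamped at 3 — so
64 channels give k = 3. The descriptor stays single-channel throughout.
Attention lives in the encoder only; the baseline ablation disables it
entirely.

### Why NumPy

The network, its gradients, and Adam are implemented from scratch in
`plaquenet.nn` (im2col convolutions, explicit backward passes). Forward
and backward are verified against central finite differences at 1e-4
relative tolerance through the full joint loss. BLAS is pinned to one
thread during training: the matrices are small enough that thread fan-out
costs more than it saves, and a fixed reduction order keeps runs
bit-reproducible.

## Objective

`L = α·L_seg + β·L_size`, with L_seg the mean per-pixel cross-entropy of
the softmax class scores and L_size the mean squared diameter error. Both
terms use mean (not sum) reduction so their balance is invariant to batch
and image size; this is a deliberate normalization choice, documented here
because the printed form of the segmentation term is a sum. The fixed mode
defaults to α = β = 1 and is used by the acceptance protocols for
determinism. The automatic mode learns two log-variances (s_seg, s_size)
and minimizes `exp(-s_seg)·L_seg + s_seg + ½·exp(-s_size)·L_size +
½·s_size`, i.e. homoscedastic-uncertainty weighting with effective
α = exp(-s_seg), β = ½·exp(-s_size); a persistently large task loss grows
its log-variance and shrinks its weight.

## Phantom generator

Each phantom holds one elliptical plaque. Geometry: the semi-long axis a
is uniform in `plaque_long_axis_range_mm` (default 2–10 mm), the aspect
ratio b/a uniform in (0.4, 0.8), orientation uniform; recorded ground
truth is the analytic (2a, 2b), so regression targets are noise-free.
Rendering: constant vessel background (0.35) plus `plaque_contrast`
(default 0.25) inside the ellipse; Gaussian edge blur (default 1.5 px);
multiplicative unit-mean Gamma speckle with shape `looks` (default 4;
variance 1/looks — 1-look speckle is the heavy-noise condition); with
probability `shadow_probability` a hypoechoic band below the plaque
(attenuation 0.3, linear feather over 6 rows / 3 columns). Defaults of
256×256 px at 0.1 mm/px are assumptions, stated here because clinical
image resolution varies by vendor. Generation is a pure function of
(config.seed, sample_index) via seed sequences.

What the phantoms do **not** emulate: real speckle correlation (the field
is i.i.d., not convolved with a point-spread function), anatomy (vessel
walls, lumen, neighboring tissue), multiple plaques, probe-motion
artifacts, and vendor post-processing. Passing the end-to-end tests
therefore demonstrates that the implementation learns and measures
correctly under the stated noise model — not clinical-grade performance.

## Split, preprocessing, augmentation

The 7:1:2 split uses a seeded permutation with floor(n·7/10) train,
floor(n·1/10) val, remainder test — the unique simple rounding that maps
287 to (200, 28, 59). Preprocessing min–max normalizes to [0, 1] (a
constant image maps to zero) and applies CLAHE (clip limit 0.02); plain
histogram equalization or no enhancement are config options. Images are
resized to the model input size (linear; masks nearest-neighbor) and the
pixel spacing rescaled accordingly.

Augmentation expands each training row into the original plus
`variants_per_image` variants (default 7, an 8-fold set), each variant
drawn uniformly from {elastic, rotate, scale, flip_h, flip_v} with
rotation ±15°, scale 0.9–1.1, elastic α = 30 / σ = 6 px. Images
interpolate linearly, masks nearest-neighbor (labels stay binary).
Diameters of augmented samples are **re-measured from the transformed
mask** rather than transformed analytically, so elastic deformation — with
no closed-form diameter law — is handled uniformly. A transform that
empties the mask is rejected and redrawn (falling back to a flip).
Validation and test rows are never augmented; a leakage guard asserts no
augmented row descends from them.

## Morphometry

Long diameter = maximum Feret diameter: the largest Euclidean distance
between boundary-pixel centers of the largest 8-connected component
(convex hull + brute force over hull vertices; exhaustively verified
against all-pairs distance). Short diameter = the component's extent
perpendicular to the long axis. Conventions: pixel-center to pixel-center
distances with no end-cap correction; degenerate extents (single pixel,
zero perpendicular width) measure one pixel. Squared pixel distances are
integers, so maximum-distance ties are exact; the perpendicular extent is
maximized over all tied axes, which makes flips and 90° rotations leave
measurements exactly unchanged. A minimum-area-rectangle alternative is
available (`method="min_rect"`). The short diameter is defined
perpendicular-to-long (not an independent caliper) — the standard
caliper-pair reading.

Two digitization facts bound the achievable agreement elsewhere: pixel
centers at the ellipse ends sit up to half a pixel inside the true
outline, so analytic ground truth and re-measured diameters agree to about
1.1 px in the worst case (tests assert 1.25 px); and k-fold
pixel-replication upsampling genuinely grows the digitized shape by
(k−1)/k px, so scaling covariance is asserted at 2/k px for k = 2 and at
√2·(k−1)/k for k = 3.

## Training protocol

Adam (lr 0.001), batch 16, up to 100 epochs with early stopping (patience
15 on validation total loss) and best-on-validation checkpointing; N
repetitions (default 10) re-initialize weights on a fixed split —
re-splitting per repetition would conflate sampling variance with
initialization variance — with per-repetition seeds
`seed + repetition_index`; metrics aggregate as mean ± std (n−1).
Segmentation metrics pool confusion counts over all test pixels
(micro-averaging; macro available via flag). The baseline arm trains the
identical trunk with attention off and no regression branch (β = 0) and
derives diameters by morphometry on predicted masks; empty predictions are
excluded and counted.

## Desk-scale protocol sizes

`plaquenet.protocols` fixes a smoke-scale study sized for minutes on one
CPU core: 64×64 phantoms at 0.12 mm/px with diameters 2–5.2 mm, 160 images
split 7:1:2, ×3 augmentation, a depth-3 / 8-channel trunk, 10 epochs. The
paired heavy-speckle comparison (1-look) uses 3 replicates at 8 epochs
with ×2 augmentation, both arms on identical data and budget. These sizes
are the package's own desk-scale choices; every knob scales up through the
same interfaces (a full-scale config would use the defaults above:
depth 4, 64 base channels, 100 epochs, 10 repetitions, ×8 augmentation).

## Numerical and degenerate-input choices

Cross-entropy clamps probabilities at 1e-300 before the log; losses are
computed in float64 while network weights are float32 (float64 available
for gradient checks). A class absent from both masks contributes IoU = 1
(vacuous agreement); two empty masks give Dice = 100. R² is undefined for
zero-variance truth and reported as missing with a warning. Constant
images normalize to zero. He-normal initialization throughout; max-pool
backward routes to the first argmax; BatchNorm uses momentum 0.1 and eps
1e-5, and its running statistics mean validation loss can change even
under frozen weights (relevant to early-stopping tests).

## Known limitations

* The i.i.d. speckle model is statistically testable but not acoustically
  realistic; no RF signal chain or point-spread function is simulated.
* The dual-branch reading ("segmentation head + regression branch over a
  shared encoder, fused by the shared trunk and the joint loss") is one
  realization of a loosely specified cross-fusion idea; alternatives
  (explicit feature exchange between branches) are not implemented.
* The NumPy backend is single-core and unsuitable for clinical-scale
  training; the architecture is deliberately framework-agnostic and small.
* Pixel spacing is assumed isotropic; anisotropic spacing would need a
  two-component spacing through morphometry and resizing.
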