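# Methods

This note documents the models, numerical conventions and design choices
behind `mriwave`. It is the place to look when a default seems arbitrary or a
result needs interpreting.

## The problem

Periodic artifacts in structural brain MRI — Gibbs ringing at high-contrast
boundaries, herringbone (spike) banding from RF interference, and zipper
stripes — originate as localized disturbances of k-space (the Fourier domain
of the image) or as structured noise in the image domain. Because clinical
datasets with annotated artifacts are essentially unavailable, the package
takes the simulation route: corrupt clean images with controllable,
physically motivated operators, and train a network to undo the corruption
with full knowledge of the ground truth.

## Synthetic phantoms

`generate_phantom_volume` produces brain-like 3D volumes: nested smooth
ellipsoidal shells with piecewise-constant per-class intensities
(CSF/GM/WM-like, raw scale ≈ 0–300), an exactly zero background, a smooth
multiplicative bias field, and additive Gaussian noise. Every draw is a pure
function of the integer seed.

Why these features and not others:

* **Sharp shell boundaries** put genuine energy into the outer radial band
  of k-space, so ringing-style attenuation there has a measurable effect.
* **Raw scale 0–300** makes the zipper noise intensities (15–50 raw units)
  a meaningful relative perturbation, as they would be on scanner data.
* **Exact zero background** makes percentile-based tissue masks behave as
  they would on skull-stripped data.
* **No MR physics**: no sequence modeling, coil sensitivities or Rician
  noise. Defaults: 64³ voxels (evaluation grids elsewhere are larger; all
  k-space geometry is expressed in Nyquist fractions so parameters
  transfer), `noise_sd = 4`, `bias_amp = 0.1`, 3 tissue classes.

What passing tests on phantoms do **not** show: robustness to anatomy-scale
texture, partial-volume effects, or artifacts that deviate from the
symmetric, strictly periodic generative model below. Conclusions transfer to
real data only to the extent that real artifacts resemble these idealized
ones.

## Corruption operators

All three operators take a `Volume` plus an `ArtifactSpec` (kind, axis,
parameter map, seed) and are deterministic given both. Parameters are
sampled once per volume, so severity is coherent across slices. Radii and
displacement distances are stored as fractions of the Nyquist radius; the
reference ranges are quoted for 256-voxel grids (Nyquist radius 128).

**Ringing.** Each slice's centered spectrum is multiplied by α inside the
sector θ ∈ [θ₁, θ₂], r ∈ [rᵢ, rₑ] *and* its point mirror (two symmetric
sectors keep the spectrum Hermitian, hence the image real). The attenuation
α = clamp(½·sin(π(1−rᵢ/rₑ)^0.55 − π/2) + ½U, 0, 1) with U ~ Uniform(0,1)
drawn once per volume from the spec seed; the exponent reading of the
"0.55" and the clamp keep α a valid attenuation in [0, 1]. θ₁ = θ₂ is
allowed as a degenerate empty sector (identity).

**Herringbone.** A ks×ks kernel copied from around the k-space center is
written, scaled by β = S/100, at a position displaced by d along one of the
four axis directions (`selection_point`); the conjugate-mirrored kernel is
written at the point-symmetric location and the spectrum is
Hermitian-symmetrized (a no-op when the two blocks do not overlap). β grows
with the smoothing parameter S, which is what makes S the severity
parameter. The displacement is clamped to at least the kernel radius plus
one pixel: the spike is by construction *off-center*, and letting the kernel
overwrite the DC coefficient would model a global brightness change rather
than a banding pattern (on small grids the unclamped ranges would overlap DC
for most draws).

**Zipper.** Uniform noise n ~ U(−1, 1) over the whole volume, added at
amplitude i inside each of `n_artifacts` stripe intervals along the
propagation axis and at i/2 elsewhere. Stripe k starts near (k+½)·T/n with
jitter uniform in ±variability/2 (pixels on the reference grid, rescaled),
and has width amplitude·U. Stripes falling partially outside are clipped and
logged. The inside/outside variance ratio is analytically i²/3 ÷ (i/2)²/3 = 4,
which the tests verify.

**Severity stratification.** mild/moderate/severe labels come from the
p25/p75 quantiles of the severity parameter over the evaluated spec
population: S for herringbone, raw intensity i for zipper, and the
attenuation depth 1−α for ringing (α = 1 is the identity, so depth — not raw
α — is what orders corruption strength). Boundary values: ≤ p25 mild,
≥ p75 severe.

## Wavelet bands

Level-1 separable 2D DWT with orthonormal Daubechies filters db1–db6; the
four sub-bands are fixed in the order (AA, AD, DA, DD), with AD =
approximation along rows, detail along columns. The filter bank is built
from the standard extremal-phase scaling coefficients with the
quadrature-mirror highpass h[k] = (−1)^k l[2L−1−k], and handed to PyWavelets
as a custom wavelet so the transform uses exactly those taps.

Boundary handling is **periodization**: a side of length N yields bands of
exactly N/2, which the four-level pooling ladder of the U-Net requires
(half-sample symmetric extension would give ⌈(N+2L−1)/2⌉-sized bands and
break the skip-connection geometry). Perfect reconstruction holds to
< 1e−8 across families and sizes; odd sides are edge-padded before the
transform and cropped after the inverse, with the original shape recorded in
the `BandSet`.

**WaveletLoss** is the band-weighted L1: Σ_b w_b · mean|pred_b − truth_b|,
with the mean over batch and spatial dimensions. Default weights
{AA: 0.1, AD: 0.3, DA: 0.4, DD: 0.3} push the correction toward the
high-frequency bands where periodic artifacts concentrate; the weights sum
to 1.1 and are deliberately not renormalized.

## Radon orientation normalization

The dominant orientation of a slice is estimated as the argmax over a
1-degree grid of the projection-variance profile of its high-pass residual
(slice minus a σ = 2 Gaussian blur), computed from the sinogram restricted
to the inscribed circle. Confidence is (max − median)/(median + ε); a
constant slice returns (0°, 0).

Two numerical points:

* The discrete Radon transform is not rotation invariant — interpolation
  smooths oblique projections more than axis-aligned ones — so per-angle
  variance gains are calibrated once per image shape on a fixed-seed
  white-noise reference and divided out. Without this, isotropic inputs
  show a structured profile with max/median ratios up to ≈ 2.5.
* Alignment rotates the estimated direction to 90° so the pattern varies
  along rows and lands in the DA band — the band with the largest loss
  weight and the monitored per-band MAE. Rotation is bilinear with zero
  padding at fixed shape; right-angle multiples take an exact
  index-permutation path; the round trip is exact to < 2 % of the dynamic
  range over the central half of the slice.

The **Radon peak ratio** on residual maps uses the same gain-normalized
profile: max score / (median score + ε), floored at 1. Oriented gratings
score ≫ 5, white noise ≤ 2 in ≥ 95 % of draws, an all-zero residual exactly 1.
A single dominant angle is assumed; multi-oriented residuals are averaged
over, which is a known limitation.

## The four-band attention U-Net

Input is the (B, 4, H/2, W/2) band stack. Four encoder levels of DoubleConv
(3×3 conv → batch norm → LeakyReLU slope 0.2, twice) with 2×2 max pooling,
a bottleneck (1024 filters by default), and four decoder levels with
bilinear ×2 upsampling, attention-gated skip concatenation and DoubleConv;
a 1×1 head maps back to four bands. Encoder widths default to the doubling
ladder 64/128/256/512 (only the bottleneck width is a fixed design point, so
the parameter count is logged, not asserted). With one DWT halving and four
poolings, slices must be ≥ 32×32.

The attention gate follows the additive formulation: θx = strided 2×2
convolution of the skip features, φg = 1×1 convolution of the coarser
decoder gating signal, ψ = σ(1×1(ReLU(θx + φg))) — a single-channel map in
(0, 1) — upsampled and multiplied into the skip features. Intermediate
channels default to half the skip width.

**Residual head.** The model predicts band *corrections*: output = input
bands + head output, with the head zero-initialized so an untrained network
is exactly the identity. This is the standard design for denoising CNNs and
gives training an honest starting point (initial SSIM equals the corrupted
input's). It can be disabled via `ModelConfig.residual`.

**Backend.** No deep-learning framework is used: the package carries a
small reverse-mode autodiff core (float32, numpy) implementing exactly the
operator set above. conv2d forward/backward are verified against a float64
reference to machine precision; bilinear upsampling is an explicit linear
operator whose backward is its exact transpose; batch-norm keeps running
statistics for eval mode.

**Training.** Adam (default lr 1e−4; the smoke-scale runs in the tests use
1e−3), batch size 8, band-weighted L1 only. SSIM/PSNR/MAE are monitored on
the image-domain reconstruction (IDWT, inverse rotation) entirely outside
the autograd graph — disabling the monitor changes no weight bit. The
best-validation-loss epoch is checkpointed; early stopping has patience 5
(the epoch budget defaults to 50 but the loss curves flatten much earlier
at desk scale). Identical seeds reproduce histories bit-for-bit.

Desk-scale problem sizes used by the test suite and acceptance checks:
200 paired 64×64 slices from 10 phantom volumes, encoder widths
16/32/64/128 with a 256 bottleneck, 3 epochs, 3 seeds — chosen so the
learning-signal check measures the pipeline, not hardware.

## Partition auditing

Per-slice features inside an automatic tissue mask (above the slice p25,
largest connected component): moments, percentiles {1, 5, 25, 50, 75, 95,
99}, a 64-bin z-score histogram; db2 band energies with detail/approximation
and Fourier high/low energy ratios (low = centered disk of half the Nyquist
radius); and GLCM texture (32 gray levels, unit offsets at 0/45/90/135°,
symmetrized, normalized per orientation then averaged; contrast,
homogeneity Σ P/(1+|i−j|), energy Σ P², ε-guarded correlation,
dissimilarity — note these are the textbook definitions, which differ from
scikit-image's homogeneity and energy conventions).

Features are pooled-z-scored and covariance-whitened (one transform applied
to both partitions; zero-variance features must be dropped or a ridge set).
Three two-sample statistics compare train vs validation: energy distance
(standard all-pairs cross term), unbiased RBF-MMD with the median-heuristic
bandwidth over distinct pooled pairs (for equal sample sizes the
index-paired cross diagonal is excluded, so identical multisets give exactly
zero), and order-1 sliced-Wasserstein over random unit directions with the
larger sample subsampled per direction to K = min(n, m). Significance comes
from a stratified permutation test (labels shuffled within artifact-kind
strata, partition sizes preserved, add-one correction). Type-I error is
calibrated to [0.03, 0.07] at nominal 0.05 in simulation; power against a
1σ mean shift at n = m = 200 is essentially 1.

## Evaluation metrics

All image metrics operate in the z-scored intensity space used for
inference. SSIM uses a Gaussian window (σ 1.5, 11 taps, K₁ = 0.01,
K₂ = 0.03, reference data range) and matches scikit-image's implementation
to < 1e−6. PSNR uses peak = reference dynamic range and caps identical
images at 100 dB so tables stay numeric. Band MSEs are reported per band
plus their unweighted mean. Edge metrics operate on Sobel gradient
magnitudes: PSNR/SSIM on the maps, mean-L1 and RMS gradient errors, and
Dice overlap of binary edges thresholded at the 90th percentile of the
reference gradient (both-empty edge sets define Dice 1). Residual
periodicity uses the Radon peak ratio above.

Paired gains Δ = out − in per slice are summarized with a percentile
bootstrap 95 % CI (default n_boot = 2000) and a two-sided sign-flip
permutation test with add-one correction (default n_perm = 10 000).

## Orchestration

`make-dataset` emits clean/corrupted NIfTI pairs plus a manifest CSV
carrying the full parameter JSON for bit-exact replay; severity labels come
from the manifest's own spec population, and the subject-level stratified
split (80/20 by default) happens before any slicing. `train` respects the
manifest split, logs the pipeline order (rotate → DWT → network → IDWT →
inverse rotate), and writes history CSV + checkpoint. `evaluate` scores
input-vs-GT and prediction-vs-GT per slice and groups by kind, severity and
mixture. `audit-split` runs the three permutation tests and writes the
table plus PCA/histogram figures. `wavelet-select` is the reduced-scale
db1–db6 comparison: per family and seed, the image-domain SSIM/MAE at the
lowest-validation-loss epoch, aggregated as mean ± sd and ranked by SSIM.

Clean and corrupted volumes are z-scored independently, each with its own
μ and σ (the normalization is per-volume preprocessing; whether pairs
should share statistics is genuinely open, and the independent choice is
the stated transform applied uniformly).

## Known limitations

* Artifacts are symmetric, strictly periodic k-space constructions;
  irregular or locally varying real artifacts are outside the generative
  model.
* Orientation normalization assumes one dominant angle.
* 2D slice-wise processing ignores inter-slice coherence.
* The numpy backend is single-threaded BLAS-bound; it is meant for
  correctness and desk-scale experiments, not production training.
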