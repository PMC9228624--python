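# Methods

## Degradation model and scope

A recorded fluorescence image is modeled as M = P ⊗ S + N: the true light
distribution S convolved with the system PSF P plus measurement noise N.
The chain here does not attempt to invert this model on the intensity
image. Instead it extracts the *support* of the filamentous structure — a
logic matrix — and returns the measured intensities on that support. All
stages after the initial 3D expansion operate slice-wise in 2D.

## Optical model

The PSF is modeled as an isotropic 2D Gaussian. Two radii derive from the
objective: the lateral radius r⊥ = 0.61 λₑ/NA and the axial radius
r∥ = 4 n λₑ/(2 NA²). Defaults describe the reference system (100× oil
immersion, NA 1.4, λₑ = 640 nm, n = 1.515 for immersion oil, which the
acquisition description implies but never states): r⊥ ≈ 278.9 nm,
r∥ ≈ 989.4 nm.

The deconvolution PSF radius is Δr = ξ·r⊥ with ξ an empirical coefficient.
ξ is deliberately larger than 1 because the outline being deconvolved has
been widened by band-limited reconstruction and thresholding; the system
PSF alone under-describes that broadening. ξ = 2.5 is the default
(undersized ξ fragments the skeleton — covered by a test); it must be
re-tuned for a different optical system.

## Expansion (Gaussian interpolation)

Up-sampling by integer factors uses normalized Gaussian-weighted
interpolation: each output voxel is Σᵢ wᵢ Iᵢ / Σᵢ wᵢ over input samples
within 3 radii, with separable weights exp(−d²ₓᵧ/2r⊥²)·exp(−d²_z/2r∥²)
evaluated at physical distances. On a regular grid these normalized weights
factorize exactly into per-axis 1D resampling matrices, which is how the
operation is implemented (three tensor contractions). Consequences:

* every output value is a convex combination of input values — the output
  range never exceeds the input range;
* the Gaussian amplitude g₀ cancels in the normalization;
* border windows renormalize over the samples they actually contain, so no
  dark frame appears;
* factor 1 on all axes is special-cased to an exact identity;
* at coinciding grid points the interpolant reproduces a smooth field to
  well under 1%, but it is a weighted average, not an exact interpolant —
  on data varying at the kernel scale it smooths.

Pitches divide by the factors: 250 nm / 4 = 62.5 nm (often quoted rounded
as 63 nm; the implementation keeps 62.5 exactly and phantom work uses a
63 nm pitch directly).

## Wavelet scale-band extraction

Standard separable 2D multiresolution analysis (Mallat), PyWavelets
backend, symmetric (half-sample) boundary extension — chosen because it
avoids the edge ringing a periodic or zero extension would inject into the
threshold stage. Default basis Coiflet-3, 6 orders. A structure of width w
pixels concentrates its detail energy around order log₂ w, so the band kept
is [floor(log₂ w_min), ceil(log₂ w_max)] — orders 4–6 for 16–64 px
structures. Reconstruction zeroes the approximation and all out-of-band
detail orders; the result M_d oscillates around zero and is clipped at 0
before thresholding (the retained top percentile is positive anyway).

When the requested order exceeds the advisable maximum for the image size
and filter length (e.g. order 6 on a 1024² image with the 18-tap Coiflet-3
filters), the code warns and proceeds: symmetric extension keeps the
transform perfectly invertible; only boundary localization degrades at the
coarsest orders.

## Binarization

The threshold χ is the (1 − p) quantile of the intensity distribution over
*structure* pixels (positive intensity after the band split), with
p = top_fraction = 0.15 by default. Ranking against the positive-pixel
population rather than all pixels matters: with a mostly dark background an
all-pixel percentile collapses to a near-zero threshold. The population is
a config switch (`population="all"`). Ties at χ are kept (≥ χ, inclusive).

## Richardson–Lucy deconvolution of the logic matrix

The outline M_edL is deconvolved, initialized from itself. One iteration:

    M_mid = M_k · { [M_edL / (M_k ⊗ P)] ⊗ P(−x,−y) }        (multiplicative update)
    f     = ⟨M_mid − M_k, M_k − M_{k−1}⟩ / ‖M_k − M_{k−1}‖²  (clamped to [0, 1))
    M_{k+1} = M_mid + f · (M_mid − M_k), negatives clipped to 0

* **Damping** (default 0.01): ratio deviations |ratio − 1| below
  damping × (observed dynamic range) are reset to exactly 1, freezing
  near-converged pixels and preventing noise amplification.
* **Acceleration**: f is the scalar (Biggs–Andrews-type) extrapolation
  weight from the inner products of successive update differences; f = 0 on
  the first iteration or when the previous step vanished. A switch disables
  it.
* **Numerics**: the ratio denominator is floored at 1e-12 (logic matrices
  contain exact zeros); convolution uses reflective boundaries, computed
  directly for kernels ≤ 15 px and via FFT on a reflect-padded image for
  wider kernels; negatives are clipped every iteration (extrapolation can
  undershoot), which also keeps the multiplicative structure meaningful.
* **Guards**: an empty mask raises immediately; growth of total intensity
  beyond 10× the input aborts with an over-processing error.

Initializing from the mask (rather than a flat image) means exact zeros
stay zero: the estimate can only tighten the outline, which is the desired
behavior for skeleton extraction. A flat init remains available.

With defaults (k_max = 10), the suprathreshold set {output ≥ 1} of a stroke
of width W px shrinks to roughly W/2; full convergence toward the 1–2 px
skeleton takes O(100) plain iterations, which is why the secondary
threshold at χ = 1 (selecting where deconvolution has *concentrated* mass
above the original mask level) does the final sharpening instead.

## Metrics

* PSNR = 10 log₁₀(MAX²/MSE) with MAX = 255 (the working 8-bit-equivalent
  scale used throughout); identical images report an infinite sentinel.
* SSIM: the standard configuration — 11×11 Gaussian window (σ = 1.5),
  C1 = (0.01·MAX)², C2 = (0.03·MAX)², population covariance — implemented
  via scikit-image and cross-checked in the tests against a direct-formula
  implementation.
* FWHM: half-maximum crossings on each side of the profile peak, located by
  linear interpolation between adjacent samples. The baseline defaults to 0
  (suits masked, background-free images) and is a parameter: profiles
  riding on a noise pedestal are measured above the window minimum. Note
  that at coarse sampling (σ ≈ 1 sample) the linear interpolation biases
  the width by a few percent — a property of the estimator, not the image.

## Synthetic phantom: what it emulates and what it does not

Each filament is a cubic Bézier path with endpoints on the field border and
interior control points displaced perpendicular to the chord by up to
curvature_scale × field (default 0.35) — smooth curved strokes spanning the
field, rasterized at a fixed width, overlapping freely (bundles).
Out-of-field samples of a strongly bowed path are dropped, and a path that
crosses less than about half a field side is redrawn. Defaults: 1024² field
at 63 nm pitch, six filaments of width 63 nm (1 px) and intensity 200,
giving a nonzero fraction well under 1% (sparse-structure assumption).

Degradation is Gaussian blur of physical radius 270 nm (σ = radius, per the
Gaussian form used for the optics) followed by additive Gaussian noise,
clipped to [0, 255]. The four standard corruption conditions are noise
(mean, STD) = (0,2), (20,4), (40,6), (40,10).

Choice of six filaments: the extraction keeps a *fixed fraction* of the
band-image structure pixels, so its budget per filament — and hence the
fraction of true filament pixels the final mask covers — falls as density
rises. Since the final image keeps the degraded values on the mask, the
PSNR balance is (background removed) − (filament pixels missed), and at the
mildest noise condition that balance is positive only when coverage is high
(≈ 0.9 at six filaments). Six filaments is therefore the densest default
that improves PSNR at *every* condition; denser fields still show the large
harsh-condition gains but can lose a tenth of a dB at (0, 2).

The phantom does not emulate: Poisson (photon-counting) noise,
depth-dependent or non-Gaussian PSFs, intensity variation along filaments,
3D continuity of filaments across slices, or dense network junctions at
realistic microtubule densities. Passing the verification study therefore
demonstrates the chain's behavior under the stated blur/noise model on
sparse curved filaments — not performance on dense live-cell networks.

## Verification experiments

* **Ground-truth study** (`run_ground_truth_experiment`): per condition and
  seed, generate → degrade → restore (expansion bypassed: the phantom is
  generated at the fine pitch directly) → PSNR/SSIM against the clean truth
  and FWHM of a filament profile before/after. Reported as mean ± STD over
  seeds (five by default). On one CPU the 1024-px study takes ~1 minute.
* **Resolution study** (`run_resolution_experiment`): a 256-px, 2-filament
  phantom with top_fraction 0.05, so the outline hugs an isolated filament.
  Per condition the narrowest cleanly-measurable recovered crossing is
  reported — the finest feature recovered, i.e. the achieved resolution —
  typically 1–2 px (63–125 nm) against blurred widths of ~600–1000 nm.
* **Profile measurement**: candidate sites are near-perpendicular, isolated
  filament crossings found by scanning rows (then columns, via transpose)
  of the ground truth. The degraded profile is averaged over five adjacent
  rows and its peak anchored within ±3 px of the known crossing — at noise
  STD 10 an unanchored global maximum is frequently a noise spike, which
  would spuriously shrink the "before" width. The recovered profile is
  taken on the single row: its background is exactly zero and row-averaging
  across an oblique crossing would artificially widen the skeleton.

## Known limitations

* The extraction is support-based: intensities on the skeleton are the
  *degraded* values, so PSNR gains come from background removal, not from
  restoring filament brightness.
* The skeleton width (and with it the measured resolution) scales with the
  outline width fed to deconvolution; top_fraction is the operative control
  and must be matched to the structure density, as done here by numerical
  experiment.
* χ thresholds are global per slice; intensity gradients along filaments
  can drop faint segments entirely (graceful per-slice failure, logged).
* The acceleration factor is clamped to [0, 1); unclamped extrapolation can
  destabilize the iteration on high-contrast masks.
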