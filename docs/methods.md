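# Methods

`optmorph` implements a quantitative optical projection tomography (OPT)
workflow for cells cultured in transparent 3D hydrogels: simulated
acquisition of projection series from digital phantoms, filtered
back-projection (FBP) reconstruction with center-of-rotation correction,
3D segmentation of single cells, equivalent-ellipsoid morphometry, density
and viability quantification, and a normality-gated statistical comparison
layer. This note records the models, the parameters that matter, and the
design choices made where the underlying experimental protocol leaves the
numerical details open.

## Imaging model

Bright-field OPT with telecentric illumination is modeled as parallel-beam
transmission tomography. The sample — a cylindrical hydrogel plug inside a
thin index-matched tube — rotates about the z axis; at each angle the camera
records a 2D projection whose rows are independent transverse slices.

Projections are represented **post-logarithm**: each detector value is the
line integral of the attenuation volume (the Radon transform of the slice).
This is the quantity FBP inverts directly, and it makes the simulation,
preprocessing and reconstruction contracts linear. A raw-transmission layer
(`I = I0·exp(−∫µ dl)`) is available (`attenuation_to_transmission`) and is
exactly undone by the preprocessing log step
(`transmission_to_attenuation`); under that intensity-domain route
reconstructed cells come out dark and `invert_intensity` (v → max−v)
restores the bright-cell convention. Under the default post-log route the
reconstruction is the attenuation map itself, cells are already bright, and
the segmentation chain operates on it directly.

Geometry conventions (stated to remove mirror/rotation ambiguity): volumes
are `(z, y, x)` with isotropic voxel pitch; angles are degrees,
counterclockwise, angle 0 aligning detector columns with +x; the rotation
axis passes through transverse pixel `n // 2`, the same center used by
`skimage.transform`'s projection operators, which the forward projector
matches to machine precision. The default acquisition is 400 projections at
0.9° steps over 360°; all 400 angles are used in reconstruction without
180° folding.

## Phantom generator

The generator emulates fibroblast-scale cells in a hydrogel plug:

- **Geometry** — tube inner diameter 1500 µm by default (the sample-holder
  tube), voxel pitch 5 µm (resolves 10–40 µm cells with several voxels per
  axis; the effective camera pixel size of the real instrument is not
  published, so the pitch is a declared default, configurable).
- **Cells** — ellipsoids with semi-axes drawn uniformly per axis from a
  configurable range (default 8–16 µm), uniformly random orientations
  (uniform rotations), centers uniform inside the cylinder with the
  constraint that no cell protrudes past the tube wall or the axial faces.
- **Density** — either an explicit cell count or a seeding density in
  cells/mL (study range 300,000–1,000,000 cells/mL); when both are given
  they must agree. The ground-truth registry records every cell and the
  exact realized density `n / cylinder volume`.
- **Non-overlap** — rejection sampling with a retry cap (default
  1000/cell). The test is conservative: bounding spheres must be separated
  by a clearance (default 2 voxels) surface-to-surface. This is stricter
  than pure non-overlap; it also guarantees that well-resolved cells cannot
  be merged by the morphological closing downstream, keeping ground-truth
  counts well-defined for recovery experiments.
- **Dead cells** — cell death removes membrane integrity and with it most
  bright-field contrast. A fraction of cells is flagged dead and rendered
  at `dead_contrast_factor` × the live contrast (default 0 ≤ factor < 1).
  The dead subset has exactly `round(dead_fraction · n)` members (seeded
  random choice) rather than per-cell Bernoulli draws, so the nominal
  fraction is realized exactly and mechanism experiments are not confounded
  by binomial noise. In the fluorescence channels both populations emit at
  full strength in their own channel (live stain vs dead stain).
- **Illumination bias** — a static multiplicative field `1 + a·g(row,col)`
  with `g` a sum of four Fourier harmonics of integer order ≤ 2 per image
  axis, zero-mean, normalized to max |g| = 1. Only "smooth, low-frequency,
  multiplicative" matters for exercising the homomorphic filter; the
  harmonic form is the simplest seeded realization.
- **Noise** — signal-dependent Poisson noise: `noise_scale` is the
  per-event intensity quantum, so the variance is `noise_scale × signal`
  and 0 disables it. Unbiasedness is verified by Monte-Carlo.
- **Rotation-axis misalignment** — `cor_offset_px` rigidly shifts all
  projections along the detector column axis.

What the phantoms deliberately do **not** model: refraction and scattering,
depth-of-focus blur, fluorescence emission propagation, cell clusters and
ECM texture, tube-wall contrast. Passing recovery tests therefore
demonstrates correctness of the computational chain under the stated
acquisition model, not robustness to every optical artifact of real OPT
data.

## Preprocessing

- **Homomorphic filter** (bright-field): log → 2D FFT → multiply by the
  Gaussian high-emphasis transfer function
  `H(f) = g_lo + (g_hi − g_lo)(1 − exp(−f²/2c²))` → inverse FFT → exp,
  applied with shared parameters to every projection in the stack.
  Defaults `g_lo = 0.3`, `g_hi = 1.0`, `c = 0.02` cycles/px. For strong
  bias-flattening the recommended setting is `g_lo = 0.1`, `c = 0.05`:
  the bias harmonics live below ~0.016 cycles/px while cell-scale detail
  (≳ few voxels) lies well above the cutoff, so this removes ≥ 80% of the
  bias CV while preserving local object contrast within 10% (both
  measured in the test suite).
- **Median filter / brightness adjustment** (fluorescence): per-projection
  2D median (odd window, default 3), then an affine rescale anchored at the
  0.5/99.5 percentiles onto the output range without clipping (pixel ranks
  preserved exactly). Pipeline order is median → brightness.
- **Live/dead composition**: per-angle integer-shift registration of the
  dead channel to the live channel by exhaustive normalized
  cross-correlation over ±10 px, with ties broken toward the smaller
  shift; degenerate (all-zero) projections get zero shift and a warning.

## Reconstruction

Slice-wise FBP: sinograms are shifted by −`cor_offset_px` (linear
interpolation) to center the rotation axis, ramp-filtered in the frequency
domain (optionally Hann-apodized for noisy data; `none` disables
filtering), and back-projected with π/N weighting (via
`skimage.transform.iradon`). Voxels outside the inscribed field-of-view
circle are undefined in parallel-beam FBP and set to 0.

The **center-of-rotation estimator** exploits 360° coverage: the projection
at θ+180° is the column-mirror of the projection at θ about the axis
position. Each opposed pair is registered by 1D cross-correlation with
parabolic subpixel peak refinement; half the lag, corrected for the
half-pixel difference between the mirror center `(n−1)/2` and the
back-projection center `n//2`, estimates the axis offset, and the median
over pairs (and, for stacks, over slices) is returned. On the 64³ test
phantom the estimator recovers injected offsets of ±5 px to ~0.002 px; a
manual scalar offset remains the primary input path.

## Segmentation

Threshold → close → despeckle → label, on the bright-cell volume:

- Threshold band `[t_min, t_max]`; defaults are Otsu (`t_min`) and the
  volume maximum (`t_max`), both logged.
- Closing = 3D dilation then erosion with a digital ball (default radius 1).
- Small-particle removal deletes components below `min_voxels`; the default
  is the voxel count of a 10 µm sphere at the current pitch (smallest
  plausible rounded fibroblast), logged.
- Connected components at configurable connectivity (6/18/26, default 26),
  relabeled deterministically in raster-scan first-voxel order.

Touching-cell splitting (watershed) is intentionally absent: the workflow
targets dispersed single cells, and clustered cells are a documented
limitation of the imaging protocol itself.

## Morphometry

Per cell, the radii are the semi-axes of the **equivalent ellipsoid**:
`R = √(5λ)` per eigenvalue λ of the voxel-center covariance (a continuous
solid ellipsoid has covariance a²/5 along semi-axis a), with the
within-voxel variance `pitch²/12` added to the diagonal before the
eigendecomposition — this removes most of the small-object discretization
bias (a digitized radius-10-voxel ball reports its radius to < 1%). Cells
below 8 voxels, or with degenerate (coplanar/collinear) voxel sets, are
flagged `shape_valid = false` and their smallest radius floored at half a
voxel. Then

    elongation = R_largest / R_medium,   flatness = R_medium / R_smallest,

both ≥ 1 by construction under ordered radii, scale-invariant, and stable
to < 1% across random orientations at ≥ 10 voxels per smallest semi-axis.

Sample-level metrics: density = count / analysis volume (the tube-section
cylinder used for placement, so recovery is tested against the exact
realized truth); the quantified-to-seeded density fraction is rounded to
integer percent; viability = 100·live/(live+dead) from independently
segmented fluorescence channels, reported to one decimal. Shape summaries
use median and quartiles with the linear-interpolation convention.

## Statistics

Shapiro–Wilk per group gates the family: one-way ANOVA with
Bonferroni-multiplied pairwise t-tests when every group passes at α (0.05
default), Kruskal–Wallis (tie-corrected) with Dunn's mean-rank z-tests
(Bonferroni-adjusted) otherwise. Two-group comparisons default to Welch's
t-test (unequal variances), with Student's available by flag; the pairwise
tests inside the ANOVA branch use the classical pooled-variance form.
Constant groups are rejected explicitly. Monte-Carlo checks in the suite:
the full gated procedure's type-I error stays ≤ 7% at nominal 5% on null
normal data, and the Kruskal–Wallis statistic matches a hand-ranked oracle
to 1e-9.

## Problem sizes and numerical choices

The default experiment scale is chosen so every recovery experiment runs
comfortably on a laptop-class single core: 96³ voxels at 5 µm pitch (a
480 µm section of a 400 µm inner-diameter tube) for density/viability
recovery — 18/30/60 cells at 300k/500k/1M cells/mL — and 64³ with 25 cells
for reconstruction round-trip experiments, always with the full 400-angle
acquisition. The full 1.5 mm tube at 5 µm pitch (≈ 300² transverse voxels)
is supported by the same code path, just larger.

Other numerical choices: subpixel shifts use linear interpolation;
back-projection uses linear interpolation; forward projection rotates the
volume in float32 (5× faster, error far below interpolation error) and
accumulates sums in float64; the projector clips the (nonnegative up to
interpolation) line integrals at 0; Otsu thresholds are computed per
volume; rounding of the density fraction follows the integer-percent
presentation convention.

## Known limitations

- Elongation/flatness are ≥ 1 by definition here; datasets reporting
  sub-unity quartiles for these indices must use a different operative
  radius convention, which is not reproducible from the definition alone.
- The bright-field and live-stain channels measure different cell
  compartments; cross-modality agreement is qualitative only.
- No depth-of-focus or emission-propagation modeling: fluorescence volumes
  are reconstructed with the same transmission Radon inverse as
  bright-field.
- The COR estimator assumes 360° coverage with opposed pairs present; for
  180° acquisitions only the manual offset path applies.
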