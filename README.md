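# optmorph

Quantitative **optical projection tomography (OPT)** analysis of cells in
transparent 3D hydrogel cultures — for tissue-engineering and biomaterials
labs that need cell morphology, density, distribution and viability from
mesoscale (~1.5 mm) samples that confocal microscopy cannot penetrate.

The package covers the whole computational chain and ships a phantom
simulator so every stage is testable without instrument data:

1. **simulate** — digital cell-laden hydrogel phantoms (ellipsoidal cells
   with known ground truth in a cylindrical plug) and parallel-beam
   projection acquisition: 400 projections at 0.9° steps over 360°, with
   optional multiplicative illumination bias, Poisson noise, and
   rotation-axis misalignment.
2. **preprocess** — homomorphic brightness normalization for bright-field
   stacks; median filtering, brightness adjustment and live/dead channel
   registration for fluorescence stacks.
3. **reconstruct** — slice-wise filtered back-projection (ramp/Hann) with
   subpixel center-of-rotation correction, plus an automatic COR estimator
   based on registering 180°-opposed projections.
4. **segment** — min/max thresholding (Otsu default), 3D morphological
   closing, small-particle removal, deterministic connected-component
   labeling.
5. **morphometry** — per-cell equivalent-ellipsoid radii
   `R_largest ≥ R_medium ≥ R_smallest` from second central moments
   (`R = √(5λ)` per covariance eigenvalue λ), and the shape indices

       elongation = R_largest / R_medium
       flatness   = R_medium  / R_smallest

   (both 1 for spheres, ≫ 1 for spindle-shaped resp. disk-like cells),
   plus cell density (cells/mL), quantified-vs-seeded density fraction,
   and viability `100·live/(live+dead)`.
6. **stats** — Shapiro–Wilk-gated group comparison: one-way ANOVA +
   Bonferroni pairwise t-tests, or Kruskal–Wallis + Dunn's test; Welch
   t-test for two groups; significance at P < 0.05.

See `docs/methods.md` for the imaging model, parameter defaults and design
rationale.

## Worked example

Simulate a phantom seeded at 500,000 cells/mL with 40% dead cells (dead
cells lose bright-field contrast), image it, reconstruct, segment and
quantify:

```python
import numpy as np
from optmorph import (PhantomSpec, generate_phantom, forward_project,
                      default_angles, build_sinograms, fbp_reconstruct,
                      segment_volume, cell_density, density_fraction)

spec = PhantomSpec(volume_shape_voxels=(96, 96, 96), voxel_pitch_um=5.0,
                   tube_inner_diameter_um=400.0,
                   seeded_density_cells_per_ml=500_000.0,
                   semi_axis_range_um=(8.0, 14.0),
                   dead_fraction=0.4, dead_contrast_factor=0.05, rng_seed=12)
volume, truth = generate_phantom(spec)
stack = forward_project(volume, default_angles(400), 0.0, spec.voxel_pitch_um)
recon = fbp_reconstruct(build_sinograms(stack), stack.angles_deg,
                        voxel_pitch_um=spec.voxel_pitch_um)
labels = segment_volume(recon)
quantified = cell_density(labels.n_labels, truth.analysis_cylinder_volume_ml)
print(f"seeded {truth.n_cells} cells ({truth.n_live} live), "
      f"detected {labels.n_labels}")
print(f"quantified density {quantified:,.0f} cells/mL "
      f"= {density_fraction(quantified, 500_000)}% of seeding")
```

Output:

```
seeded 30 cells (18 live), detected 18
quantified density 298,416 cells/mL = 60% of seeding
```

Bright-field OPT sees only the 18 live cells — dead cells at 5% contrast
fall below the detection threshold — so the quantified density lands at
60% of the seeding density even though segmentation is perfect. This is
the mechanism by which quantified cell densities in week-old hydrogel
cultures come out well below the seeded density while fluorescence
viability counts hover in the same 55–65% range.

The same chain is scriptable from the shell:

```bash
opt-morph fixtures --preset density_sweep --out fx/ --seed 1
opt-morph reconstruct --input fx/density_300k.tiff --out rec.tiff --cor auto --no-invert
opt-morph segment --input rec.tiff --out labels.tiff
opt-morph quantify --labels labels.tiff --out quant/
```

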