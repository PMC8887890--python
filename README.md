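# trexmetrics

Quantitative validation metrics for ten-fold robust expansion
microscopy (TREx). Expansion microscopy beats the diffraction limit by
embedding a specimen in a swellable hydrogel and physically expanding
it; a ~10× single-step protocol is only trustworthy if the gel is
mechanically sound and the expansion is isotropic at every scale. This
package implements the measurements that establish both, for anyone
developing or validating an expansion protocol:

* **Gel mechanics** — the *deformation index* of an upright
  semicircular gel punch: a circle is fitted to the digitized top edge
  and each corner's vertical drop below the circle apex is divided by
  the gel radius `R`. Index < 0.125 means excellent handling,
  0.125–0.25 acceptable, > 0.25 unacceptable. The *expansion factor*
  is expanded diameter / 6 mm cast diameter; recipe families are
  summarized as mean ± SD curves versus crosslinker concentration.
* **Distortion analysis** — a pre/post-expansion landmark
  correspondence is decomposed into a similarity transform
  `x ↦ s R x + t` (ideal expansion; `s` is the macroscopic expansion
  factor) and a residual elastic thin-plate-spline field `r(·)` in
  pre-expansion units. The measurement error between points p, q is
  `‖r(p) − r(q)‖`, binned by pre-expansion distance `‖p − q‖`.
* **Nanostructure size estimators** — Gaussian fits to radial
  intensity profiles of nuclear-pore rings (107 nm reference, the
  local expansion ruler), FWHM and peak-to-peak of 1D line scans
  (tubules, clathrin-coated pits), threshold + watershed particle
  sizing with equivalent-circle diameters `2√(area/π)` (microvilli),
  and paired-peak 3D separations of pre/postsynaptic markers.
* **Synthetic data** — seeded generators for every input, with ground
  truth recorded for recovery testing.

## Worked example

```python
import numpy as np
from trexmetrics import (gen_gel_edge, deformation_index, gen_ring_image,
                         ring_diameters, ExpansionContext, local_expansion_factor,
                         gen_landmark_field, fit_similarity, residual_field,
                         sample_field, measurement_error_curve)

# 1. a gel edge digitized with 0.05 mm noise, true sag fraction 0.13
edge, _ = gen_gel_edge(gel_radius_mm=12.5, sag_fraction=0.13, n_points=7,
                       noise_sd_mm=0.05, seed=3)
res = deformation_index(edge)
print(f"deformation index = {res.index_mean:.3f} ({res.handling_class})")

# 2. sixteen nuclear-pore rings at the 107 nm reference scaled 9.5x
pixel_nm = 13.2
r_px = 107.0 * 9.5 / 2 / pixel_nm
centers = [(50.0 + 105*i, 50.0 + 105*j) for i in range(4) for j in range(4)]
img, _ = gen_ring_image(shape_px=(420, 420), pixel_size_nm=pixel_nm,
                        centers_px=centers, ring_radius_px=r_px,
                        shell_sigma_px=4.0, amplitude=500.0, background=50.0,
                        noise_sd=50.0, seed=1)
table, summary = ring_diameters(img, np.array(centers), pixel_nm)
print(f"mean ring diameter = {summary['mean_diameter_nm']:.0f} nm "
      f"+/- {summary['sd_diameter_nm']:.1f} nm (n={summary['n_converged']})")
ctx = ExpansionContext(expansion_factor=9.5, reference_size_nm=107.0)
factor, percent = local_expansion_factor(summary["mean_diameter_nm"], ctx)
print(f"local expansion factor = {factor:.1f}x ({percent:.0f}% of expected)")

# 3. landmark field with a 0.5 um sinusoidal elastic distortion at 9.4x
lm, _ = gen_landmark_field(150, scale=9.4, elastic_amplitude_um=0.5,
                           elastic_wavelength_um=40.0, noise_sd_um=0.2, seed=2)
t = fit_similarity(lm)
curve = measurement_error_curve(sample_field(residual_field(lm, t), 5.0), seed=0)
print(f"macroscopic expansion (similarity scale) = {t.scale:.2f}x")
print(f"overall error fraction = {100*curve.overall_fraction_mean:.1f}% "
      f"+/- {100*curve.overall_fraction_sd:.1f}%")
```

prints

```
deformation index = 0.128 (acceptable)
mean ring diameter = 1016 nm +/- 0.4 nm (n=16)
local expansion factor = 9.5x (100% of expected)
macroscopic expansion (similarity scale) = 9.40x
overall error fraction = 1.6% +/- 1.3%
```

The noisy edge recovers the true sag (0.13) to digitization precision
and lands in the acceptable handling band. The ring batch recovers the
generated 107 × 9.5 = 1016.5 nm diameter, i.e. a local expansion factor
equal to the macroscopic one (100% of expected) — on real samples a
deficit here means protein-dense structures resisted full expansion.
The similarity scale recovers the generated 9.4× expansion, and the
error fraction quantifies how much of any two-point measurement the
residual elastic distortion corrupts.

A CLI mirrors the library for shell use:

```sh
trexmetrics gel deformation --points edge.csv --radius 12.5
trexmetrics distort --landmarks landmarks.csv --bin-width 5
trexmetrics rings --image rings.tif --centers centers.csv --pixel-size 13.2
trexmetrics particles --image microvilli.tif --pixel-size 0.05
trexmetrics synapses --post homer.tif --pre bassoon.tif --voxel 0.3 0.1 0.1
trexmetrics simulate --generator gen_ring_image --seed 1 --out sim/
```

Logs go to stderr and results to CSV/JSON files, so stdout stays clean.

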