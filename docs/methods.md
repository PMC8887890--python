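# Methods

`trexmetrics` implements the quantitative validation suite used when
developing a ten-fold, single-step expansion microscopy protocol: gel
mechanical characterization, registration-based expansion-distortion
analysis, and size estimators for reference nanostructures. This note
records the models, the defaults and why, the numerical choices, and
what the synthetic-data tests do and do not demonstrate.

## Gel mechanics

A semicircular punch (radius `R`, 12.5 mm for the 25 mm cutter) stands
upright on its curved edge and its straight top edge sags under
gravity. The photographed top edge is digitized as a small number of
points (seven by convention), a circle is fitted, and the **deformation
index** of each corner is the vertical drop from the fitted circle's
apex (center_y + radius) to that corner, divided by `R`, clamped at 0.
The per-gel index is the mean of the two corner indices. Handling
classes follow the calibrated thresholds: index < 0.125 "excellent",
0.125–0.25 "acceptable", above 0.25 "unacceptable".

Operational choices the measurement convention leaves open, fixed here:

* **Corners** are the first and last digitized points by x.
* **Apex** is the topmost point of the fitted circle, not the highest
  digitized point; this makes the noiseless synthetic round trip exact.
* **Circle fit** is the closed-form algebraic (Kåsa) least squares.
  Seven manually digitized points do not warrant iterative geometric
  refinement; tests show the two agree to well within digitization
  noise. Edges collinear to 1e-9 of the chord length, or with fitted
  curvature below 1e-6 /mm, are treated as straight (index 0) rather
  than failing.
* **Gel radius** is a required input (the punch radius at photo scale),
  not inferred from the corner chord, so sagging cannot bias the
  denominator.

The **expansion factor** is expanded diameter / cast diameter (6 mm
punch by default). `recipe_curves` aggregates per-gel measurements into
per-(family, crosslinker concentration) mean ± sample SD curves; a
single-replicate group reports SD 0 and is flagged.

## Distortion analysis

Matched pre/post-expansion landmarks (manually picked control points)
define a mapping decomposed into:

1. a **similarity transform** `x ↦ s R x + t` (uniform scale, rotation,
   translation; closed-form least squares, Umeyama/Procrustes form).
   Reflections are excluded — a mounted-gel flip must be corrected
   upstream. The fitted scale *is* the macroscopic expansion factor of
   the registered region.
2. a **residual elastic field**: per-landmark residuals
   `(post − S(pre)) / s`, expressed in pre-expansion (biological) µm,
   interpolated by a standard 2D thin-plate spline (kernel
   `r² log r²` plus affine term). Regularization defaults to λ = 0
   (exact interpolation at control points), matching common
   landmark-warping defaults; λ > 0 trades control-point fidelity for
   smoothness, and the misfit grows monotonically with λ.

The **measurement-error curve** evaluates the residual field on a
regular grid over the landmark bounding box (default spacing =
bounding-box diagonal / 50; dense pixel sampling is statistically
redundant), and for every pair of grid nodes (p, q) computes the error
`‖r(p) − r(q)‖` and length `L = ‖p − q‖`. Errors are binned by L
(default bin width 5 µm pre-expansion), giving per-bin mean ± sample SD
and fractional error; pairs above a cap (default 10⁶) are subsampled
without replacement with an explicit seed. On ≤ 50 nodes the vectorized
computation is verified to match a brute-force double loop exactly.

A decomposition subtlety worth recording: the fitted similarity absorbs
whatever projection the true elastic field has onto similarity modes.
The residual field therefore equals the generating sinusoid only up to
that projection; the exact invariant — and the one tested without
tolerance — is completeness, `S(pre) + s·residual(pre) = post` at λ = 0.
Held-out-point recovery of the analytic field is checked with the true
transform supplied and landmarks dense relative to the elastic
wavelength (400 landmarks, λ = 40 µm over a 100 µm box), where
thin-plate interpolation error is the only term.

## Ring diameters (nuclear pore complexes)

NUP96 rings of known 107 nm diameter serve as a local expansion ruler.
For each manually picked center, the radial intensity distribution is
computed with integer annuli: annulus k averages pixels whose
center-to-center distance falls in [k − 0.5, k + 0.5), reproducing the
integer-annulus semantics of the classic radial-profile plugin; the
profile conserves total intensity by construction. A Gaussian plus
constant is fitted to a window around the global off-center maximum —
operationalized as the contiguous above-half-maximum run (relative to
the profile floor), padded to at least 7 samples — and the fitted
center is the ring radius. Fits whose center leaves the window or
whose σ exceeds the window width are flagged unconverged and excluded
from the batch summary (with a failure count). Profiles with no
interior maximum raise a no-ring error.

The **local expansion factor** is measured diameter / reference
diameter; **percent of expected** compares it to the macroscopic
factor. All arithmetic is kept at full precision; rounding (8.8×, 92%,
1.02 µm) happens only at presentation.

## Line profiles

**FWHM**: baseline = mean of the outer 10% of samples on each side (the
measurement convention states no baseline rule; outer-decile averaging
is robust to one-sided tails), half level midway between baseline and
peak, crossings located by linear interpolation nearest the peak on
each side. A peak at the profile boundary is an error, not a guess.

**Peak-to-peak** (clathrin-coated pits, antibody-stained microtubule
sidewalls): moving-average smoothing (window 3), `scipy.signal`
peak finding at ≥ 10% of the intensity range prominence, distance
between the two most prominent peaks. Fewer than two qualifying peaks
raises an error signalling an unresolved structure.

**Peak normalization** divides by the maximum (idempotent,
gain-invariant); FWHM and peak-to-peak are invariant under it.

## Particles and synapses

**Microvilli cross-sections**: IsoData iterative-intermeans threshold
(256-bin histogram, `t ← (mean below + mean above)/2` to its fixed
point — the scheme behind the common "auto" threshold), Euclidean
distance-transform watershed seeded at distance-map maxima (minimum
separation 2 px) to split touching particles, then per-particle pixel
area → equivalent-circle diameter `2√(area/π)`. Border particles are
retained by default (matching the common particle-analysis default)
with a flag to exclude. Watershed reassigns rather than deletes
foreground; tests assert ≥ 98% pixel conservation (ridge lines account
for the remainder).

**Synapses**: each 3D channel is segmented by a fraction-of-max
threshold (default 0.5) plus 26-connected components with a minimum
voxel count — a deliberate, documented simplification of interactive
machine-learning segmentation, sufficient for synthetic volumes;
externally produced label masks (e.g. exported from an interactive
classifier) can be wrapped in `SegmentationLabels` and passed directly.
Each postsynaptic object is paired with the nearest presynaptic object
by intensity-weighted centroid distance in physical units (default
gate 2 µm, configurable); the separation is the Euclidean distance, in
µm honoring anisotropic voxel sizes, between the local intensity maxima
(26-neighborhood) closest to each mask's intensity-weighted center of
mass. A mask with no interior local maximum falls back to its in-mask
global maximum (logged, not an error). Centers of mass are
intensity-weighted throughout.

## Synthetic data

Generators produce every input the pipeline consumes, with the ground
truth recorded in a side table so tests never re-derive truth from
images. Defaults encode the conditions the measurements target: 12.5 mm
gel radius and 7 edge points; ~10× landmark scale over a 100 µm
pre-expansion field; ring radii matching the 107 nm reference scaled by
the expansion factor; 450 nm two-peak separation; ~11 px disk diameters
(microvilli at ~100 nm over ~10× at realistic pixel sizes); 1.17 µm
synapse separations with 0.2 µm blobs on 0.1 µm voxels. Where the
underlying studies do not report pixel sizes or SNR, defaults are
chosen for estimator testability (SNR ≥ 5, shells/blobs several pixels
wide) — a deliberately idealized regime.

Construction guarantees used by oracle tests: gel-edge corners sit
exactly `sag · R` below the arc apex; the elastic component is a
separable sinusoid `A(sin 2πx/λ, sin 2πy/λ)` in pre-expansion units
(simple, smooth, analytically evaluable — the real deformation's
functional form is unknown); blob pairs are displaced by exactly the
requested separation along uniformly random unit vectors. Object
placement is rejection-sampled with a 1000-attempt cap and fails loudly
naming the cap. Edge noise is vertical-only so x-ordering survives.
All randomness flows through `numpy.random.default_rng(seed)`;
identical parameters and seed reproduce outputs bit for bit.

What passing on synthetic data does **not** show: robustness to real
point-spread functions, labeling stochasticity, antibody linkage error,
background structure, segmentation of touching/irregular organelles, or
ML-quality 3D segmentation. The synthetic suite validates the
*estimators and their arithmetic*, not image-analysis performance on
real micrographs.

## Problem sizes

Recovery suites use 100 seeded rings (101² px each), 100-disk packings
on 512² px, 5 × 20 synapses on 48×160×160 voxel volumes, 300-seed
Monte-Carlo spread estimation for the noisy deformation index, and
≤ 50-node exact pairwise oracles — sizes at which the estimator
statistics of interest (bias ≲ 2%, SD stability) are already resolved.

## Known limitations

* The similarity/elastic decomposition is 2D (projected data); no 3D
  deformation fields.
* No automatic landmark, ring-center or line-scan placement; these are
  manual inputs by design.
* The IsoData + connected-components segmentation stand-in will
  under-perform interactive classifiers on real low-contrast data.
* Thin-plate interpolation error grows where landmarks are sparse
  relative to the deformation wavelength; error curves are only as
  dense as the landmarks.
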