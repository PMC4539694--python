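# Methods note

This note records the statistical model, the default parameters and why
they were chosen, what the synthetic data generator does and does not
capture, the numerical choices, and the known limitations. Problem
sizes (grid resolutions, cohort sizes, noise levels) are choices made
by this package for its phantom test bed; they were fixed once, on
realism grounds, before the end-to-end tests were finalized.

## 1. Model

### 1.1 Data model

A subject volume is generated from a deterministic analytic template
`T(x)` (world coordinates `x` in mm) as

```
V_i = g_i · [ T ∘ φ_i ] + ε_i,     ε_i(v) ~ N(0, (g_i σ)²) i.i.d.
```

where `g_i` is a per-subject global activity factor, `φ_i` a small
residual spatial deformation (what remains after spatial
normalization), and `σ` the nominal noise level. The noise standard
deviation scales with `g_i` because PET noise follows count
statistics: a globally hotter scan has proportionally larger absolute
fluctuations. This matters downstream — under median intensity
scaling the factor `g_i` then cancels *exactly*, noise included, so
global activity differences contribute no spurious between-subject
variance.

Hypometabolic lesions multiply the template by `1 − r·w(d)` where `r`
is the reduction, `d` the distance to the lesion centre, and `w` a
profile equal to 1 inside the lesion radius with a Gaussian shoulder
(`edge_sigma_mm`, default 2 mm) outside. The ground-truth mask is
`w(d) ≥ 0.5`, i.e. the full-reduction core plus half the shoulder.

### 1.2 Statistics

With reference mean `m`, sample SD `s` (n − 1 denominator) over `n`
controls and patient value `p`, at each in-mask voxel:

* direct z: `z = (m − p) / s`, clipped to `[−cap, cap]` with
  `cap = 7.9` by default (display convention; `cap=None` disables it);
* single-subject t: `t = (m − p) / (s √(1 + 1/n))`, `df = n − 1`,
  which is the exact distribution of a new observation against a
  sample mean under normality;
* exact t→z: `z = Φ⁻¹(1 − P(T_df > t))` evaluated in log space
  (`ndtri_exp(logsf)`), so it is finite and strictly monotone even at
  `t = 50, df = 100` where naive `sf` underflows;
* paired and two-sample (pooled-variance) group t-maps;
* thresholds at uncorrected `p` or Bonferroni `p / n_mask`.

A variance floor is applied when building the database: voxels whose
SD falls below `floor_fraction` (default 1 %) of the mean in-mask SD
are raised to that floor. Without it, near-deterministic voxels (deep
in uniform tissue on low-noise phantoms) produce arbitrarily large z
from negligible absolute differences.

### 1.3 Clusters and classification

Suprathreshold voxels (`z > 3`, strict) are grouped by flood fill
(default 26-connectivity; 6 and 18 available). A scan is classified
**positive** iff its largest cluster strictly exceeds the size
threshold, default 250 voxels on the 2 mm grid (2 cm³). The strictness
of both inequalities is load-bearing and tested: a value exactly 3 or
a cluster of exactly 250 voxels does not trigger.

### 1.4 Surface projections

The surface model is the boundary of the brain mask (mask voxels with
an out-of-mask 6-neighbour); the single connected component is
required. For each vertex the projection takes the **maximum** volume
value along the inward normal, sampled at depths 0, 2.25, …, 13.5 mm
(7 samples), which makes cortical hypometabolism visible from outside
regardless of its exact depth. Eight canonical views (left/right
lateral and medial, anterior, posterior, superior, inferior) are
rasterized; SSP z-scores compare per-vertex projected values against a
vertex-wise reference built the same way from the control cohort.

### 1.5 Spatial normalization

Registration is intensity-based least squares on Gaussian pyramids:

1. **Affine (12 parameters).** Translation, rotation, scale, shear,
   optimized by Powell's method on a coarse-to-fine pyramid
   (default 8 mm then 4 mm smoothing).
2. **B-spline refinement.** Two-step coarse-to-fine cubic B-spline
   displacement fields with control-point spacings 30 mm then 15 mm,
   gradient descent with an analytic data-term gradient.
3. **DCT refinement.** A low-frequency cosine basis (7×9×7
   coefficients per component) refines the residual, mirroring the
   classic SPM-style small-deformation parameterization.

Warps are penalized by `reg_weight · mean((u / 10 mm)²)`; the 10 mm
reference length makes the default `reg_weight = 0.01` unit-free and
interpretable (a uniform 10 mm displacement costs 0.01 in units of the
normalized image variance). Transforms are pull-backs (target world →
source world); see the coordinate section of the README.

## 2. Default parameters and rationale

| Parameter | Default | Rationale |
|---|---|---|
| z cap | 7.9 | display convention for clinical maps; beyond ~8 SD the magnitude is not informative |
| cluster threshold | z > 3 | ≈ p < 0.0013 one-sided per voxel |
| cluster size | 250 voxels @ 2 mm | 2 cm³; small enough for focal deficits, large enough that phantom null scans stay below it |
| smoothing FWHM | 10 mm | standard single-subject FDG-PET practice; dominates scanner PSF and residual misregistration |
| scaling target | mask median = 100 | robust to focal deficits (a lesion barely moves the median, unlike the mean) |
| variance floor | 1 % of mean mask SD | guards near-deterministic voxels; ≤ a few % of mask voxels affected at the frozen noise level |
| connectivity | 26 | standard for cluster reporting in volumetric neuroimaging |
| B-spline spacings | 30, 15 mm | coarse-to-fine; 15 mm is the finest scale the 10 mm-smoothed data can constrain |
| DCT basis | 7×9×7 | ≈ one basis function per 26 mm per axis on the MNI-like field of view |
| reg_weight | 0.01 per (u/10 mm)² | mild; prevents mask-edge oscillation without biasing recovered amplitude |
| reg_scale_shear | 1.0 | affine penalty on log-zooms² + shears²; removes the rotation-vs-shear degeneracy (§4) |

### Frozen study conditions (phantom cohorts)

Chosen once for the end-to-end tests and the acceptance script:

* **n = 37 controls** — typical size of a single-centre normal
  database.
* **texture_amplitude = 8** (≈ 8 % of cortex intensity) —
  deterministic smooth texture so registration has features to lock
  onto and scans are not implausibly flat.
* **noise σ = 10** (10 % of cortex = 100) — realistic single-subject
  FDG-PET noise after reconstruction.
* **residual warp 0.25 mm RMS** — the anatomy that normalization
  *cannot* remove. Published normalization accuracy is a few mm;
  most of that is removed again by the 10 mm smoothing, and 0.25 mm
  RMS is the post-smoothing residual consistent with the package's own
  warp-recovery accuracy.
* **global activity factor g ~ U(0.85, 1.15)** — ±15 % global
  variation, removed exactly by median scaling (§1.1).
* **Acceptance lesion at shell fraction 0.85 of the cortical shell,
  radius 8 mm, reduction 30 %** — placed so the ground-truth sphere
  lies entirely inside the grey+white analysis mask. At the default
  cortical-point depth (fraction 0.94) roughly a quarter of the
  lesion volume falls outside the mask and is undetectable *by
  construction*, which caps the attainable Dice below 0.5 regardless
  of method quality. The 0.85 placement is a measurement-validity
  requirement (the truth must be inside the instrument's field of
  view), not a tuning of the method.

Honesty note on null behaviour: across 12 probe seeds of unlesioned
patients under these conditions, 11 produced a largest null cluster
below 250 voxels; one probe seed reached 272. The canonical unlesioned
test case (seed 10000, largest cluster 83) is well within the rule, but
the per-scan false-positive rate of the z>3 / >250-voxel rule under
these phantom conditions is of order 1/12, not zero. Real reference
databases face the same issue and typically mitigate it by larger n
and reader review.

## 3. Generator realism and limits

Captured: tissue contrast hierarchy (cortex > WM > deep nuclei; CSF
cold), left–right mirror symmetry, global activity variation with
count-scaled noise, residual misregistration as smooth random warps,
focal hypometabolism with soft edges and exact ground truth,
reproducible cohorts from a single seed.

Not captured: true gyral anatomy (the "cortex" is an ellipsoidal
shell; texture is smooth noise, not sulci), partial-volume effects of
a finite scanner PSF (phantom values are point samples, not
resolution-blurred), attenuation/scatter artefacts, correlated
reconstruction noise (phantom noise is voxel-wise i.i.d.; real FBP/OSEM
noise has spatial correlation, which inflates cluster sizes — one
reason the null-cluster margin above should not be over-read),
anatomical variability beyond smooth warps (no atrophy, no
ventricular enlargement), and arterial-input/kinetic effects (the
global factor is a scalar).

## 4. Numerical choices

* All statistics are computed in float64; the reference database is
  stored in float64 NIfTI by default (bit-exact round trips are
  tested). Int16 export with slope scaling is available for
  interchange.
* `t_to_z` goes through `log(sf)` and `ndtri_exp`, not `sf` and
  `isf`, to stay exact in far tails; verified against adaptive
  quadrature of the t-density to 1e−6 absolute.
* Z capping is a final `np.clip`; a 20-SD deviation maps to exactly
  7.9 (tested as equality, not approximation).
* Interpolation is trilinear (nearest-neighbour available for label
  volumes). A forward+inverse affine resampling round trip loses
  < 2 % RMS of the dynamic range on the 2 mm MNI-like grid; at 4–6 mm
  the double-interpolation error exceeds that bound, which is the
  usual resolution argument for normalizing at 2 mm.
* Powell's method was chosen for the affine because the 12-dim
  objective on smoothed phantoms is smooth but its analytic gradient
  with respect to pose is not worth maintaining; the pyramid makes the
  basin wide. Recovery is ≤ 1 mm / ≤ 0.5° over sampled offsets up to
  ±10 mm / ±5° (tested on 10 seeded draws).
* The 12-parameter MSE objective has a genuine rotation-vs-shear
  degeneracy: a small shear (~0.02) plus a compensating rotation can
  fit a rigidly moved image *better* than the true pose, the gain
  being at the level of the trilinear interpolation-error floor. The
  affine is therefore regularized toward rigidity
  (`reg_scale_shear = 1.0` times the sum of squared log-zooms and
  shears), the same idea as SPM's priors on zooms and shears. The
  penalty does not suppress genuinely affine fits: an unmodeled shear
  of 0.02 misaligns the cortex by ~1.6 mm, costing roughly 30× more
  in the data term than the penalty charges for modelling it. On the
  texture-free near-ellipsoid phantom some rotation components remain
  weakly identified by intensities alone — a property of the phantom,
  not the method — so the recovery tests register the textured
  template.
* Warp refinement uses explicit analytic gradients of the SSD data
  term through the interpolator; the B-spline and DCT recoveries
  correlate > 0.8 with a planted 4 mm-RMS, 40 mm-FWHM smooth field.
  The 40 mm smoothness matches the low-frequency bases; recovering
  sharper fields than the basis can represent is ill-posed by design.
* Flood-fill clustering is implemented with an explicit stack over
  precomputed neighbour offsets and is tested for exact component
  equality against an independent pure-Python flood fill across all
  three connectivities.
* The exact Wilcoxon signed-rank comparison of cluster sizes requires
  tie-free |differences| and enumerates sign patterns for small
  samples (scipy's exact mode is used through `compare_cluster_sizes`;
  the test oracle enumerates independently).

## 5. Open decisions

* **Scale-then-smooth order.** The pipeline scales intensities before
  Gaussian smoothing. For the global median scaling used here the two
  orders are nearly (not exactly) equivalent; region-mean scaling on a
  small reference region is more order-sensitive. The order is fixed
  and documented rather than configurable.
* **Surface model.** The boundary-voxel surface with 6-neighbour
  normals is deliberately simple; a marching-cubes mesh with smoothed
  normals would render prettier SSPs but adds a mesh dependency
  without changing the statistics.
* **Single-level size threshold.** The 250-voxel rule is global; a
  region-wise (lobar) threshold would better match reader behaviour
  but needs a finer atlas than the phantom provides.

## 6. Limitations

* The phantom's geometric simplicity means registration problems are
  easier than on real anatomy; the recovery bounds in §4 should be
  read as sanity checks of the implementation, not as expected
  clinical accuracy.
* The null-calibration test (§2 honesty note, and acceptance test 7)
  validates voxel-wise rates under i.i.d. noise; spatially correlated
  noise would need random-field or permutation thresholds, which are
  out of scope.
* The classification rule is a hard threshold pair with no reader in
  the loop and no multi-scan longitudinal logic.
* Only axis-aligned grids are supported; oblique acquisitions must be
  resampled upstream.
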