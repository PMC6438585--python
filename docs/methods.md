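# Methods

This note documents the models, conventions and numerical choices behind
the pipeline, what the synthetic cohort does and does not emulate, and the
known limitations.

## Image and VOI model

A PET volume is a 3D array of standardized uptake values (SUV, unitless,
≥ 0) with anisotropic voxel spacing, default 4.07 × 4.07 × 2 mm (voxel
volume 0.0331 ml). Arrays are indexed `(i, j, k)` over `(x, y, z)`; world
coordinates follow the NIfTI affine. VOI masks are boolean arrays on the
same grid, stored as 0/1 uint8 NIfTI, and round-trip bit-exactly. A VOI is
analyzable for texture only if it has ≥ 64 voxels (2.12 ml at the default
spacing) and forms a single 26-connected component; smaller or fragmented
VOIs raise explicit errors and are counted as exclusions by the study
driver. The voxel floor is primary; the ml figure is derived from spacing.

## Synthetic cohort

Each phantom is built in a fixed order: ellipsoid indicator at the peak
SUV → multiplicative textured heterogeneity → necrotic core carved to
background → background plateau outside the tumor → Gaussian blur →
additive Gaussian noise → clamp at 0. Deterministic given its seed.

* **Heterogeneity** is a Gaussian random field: white noise smoothed with a
  Gaussian of FWHM `texture_corr_len_mm` (default 8 mm), standardized over
  the tumor support, applied as `1 + amp·field` (default amp 0.4, clipped
  below at 0.05 so uptake stays positive).
* **Blur** default is 6 mm FWHM — the effective resolution of a PET system
  plus post-filter, not the 2 mm post-smoothing alone; phantoms must show
  partial-volume behavior for the threshold methods to differ.
* **Noise** is additive Gaussian in SUV (default SD 0.1 against a
  background of 1.0). Reconstruction (Poisson/OSEM) noise correlation is
  deliberately not modeled.
* **Cohort defaults**: 43 patients; true volumes log-uniform over 3–60 ml,
  except a 30% fraction drawn at 0.5–2 ml, below the 64-voxel floor, to
  exercise the exclusion accounting (≈ 29 of 43 survive all methods);
  per-patient SBR normal around 23.5 ± 7.4 (clipped to [8, 45]) against a
  fixed background of SUV 1; 30% of tumors get a necrotic core spanning
  20–50% of the radius; mild random ellipsoid elongation (axis ratios
  0.85–1.18) and sub-voxel center jitter.
* **Observers** differ only by a random displacement of the nominal seed
  click: direction uniform on the sphere, magnitude uniform in
  [0, jitter_mm] (default 4 mm ≈ one transaxial voxel), constrained inside
  the tumor support.

What this does *not* emulate: scanner reconstruction artifacts, dental
artifacts, respiratory motion, lesion-adjacent physiological uptake, or
clinically realistic SUVmax distributions. Passing tests therefore show
that the pipeline's statistics behave correctly under controlled,
PET-like contrast and noise — not that the specific index values transfer
to patient data.

## Segmentation

All methods work inside a spherical search region (default radius 60 mm)
around the observer's click — the explicit stand-in for the physician
restricting attention to the lesion. Every returned mask is reduced to one
26-connected component: the component containing the hottest masked voxel
wins; exact SUV ties go to the larger component, residual ties to the
lowest label. Consequently every method's mask contains the regional
maximum and SUVmax is invariant across methods and observers.

* **Fixed threshold**: voxels ≥ 40% of the search-region SUVmax
  (inclusive ≥).
* **SBR estimate**: lesion SUVmax over the mean SUV of a shell lying
  between 8 and 20 mm of physical (EDT) distance from the mask — the guard
  ring keeps spill-out from contaminating the background.
* **Adaptive threshold**: iterate from the 40% mask: measure SBR, set the
  fraction `t = a/SBR + b` (clamped to [0.2, 0.8]), re-threshold at
  `t × core mean`, where the core mean is the mean SUV of voxels above 50%
  of the regional max. The core mean, not SUVmax, is the reference signal:
  it is robust to noise spikes and to heterogeneity-inflated maxima, which
  is what lets an adaptive method out-segment a fixed 40%-of-max rule on
  textured lesions. Fixed point is typically reached in 2–3 iterations;
  after 10 the last mask is returned with a warning flag.
* **Calibration** of `(a, b)`: for each (volume, SBR) pair on a grid of
  noiseless blurred spheres (defaults 6/12/20/32 ml × SBR 8/15/25/40), the
  volume-recovering threshold level is measured as the mean image value on
  the true boundary radius (the continuum form of "the isocontour that
  encloses the true volume"; reading the level off sorted voxel
  intensities is quantized at the ±0.05 level on a 4.07 mm lattice because
  voxel radii come in lumpy shells). Calibration spheres are placed
  slightly off the grid symmetry point for the same reason. The level as a
  fraction of the core mean is regressed on 1/SBR; with no SBR variation
  the law degenerates to its intercept. Fit residuals are ≈ 0.02; held-out
  spheres of 8–40 ml are recovered to ≈ 1%.
* **Gradient edge**: smooth at 2 mm, cast 200 Fibonacci-lattice rays from
  the observer's click, sample radial profiles at 0.5 mm steps, and take
  per ray the *outermost* local minimum of the radial derivative whose
  magnitude reaches half the strongest descent (intratumoral texture
  creates inner edges; the lesion rim is the outermost comparable one).
  Rays with no significant extremum (flat profile, or extremum at the
  search limit) are invalid; more than 20% invalid rays is an error,
  fewer are filled with the median boundary radius. The star-shaped
  interior is voxelized by interpolating boundary radii over the 4 nearest
  ray directions, then morphologically closed. Anchoring the rays at the
  click (rather than at the max voxel) is what makes this method
  observer-sensitive — threshold methods depend on the click only through
  the search region, so their two-observer masks typically coincide, while
  the gradient contour shifts with the click; in the default study this
  reproduces the clinical observation that gradient-based delineation is
  the least observer-reproducible.

## Discretization and texture matrices

Absolute resampling: `level = 1 + floor(64·(clamp(v, 0, 30))/30)`, with
v = 30 mapping to level 64 and values above 30 clamped — identical bins
for every lesion, no spatial resampling. Gray levels are 1-based so the
low-gray-level emphases are always defined.

* **GLCM**: distance 1 voxel, the 13 unique 3D directions in both signs,
  accumulated into one symmetric 64 × 64 matrix, then normalized. Indices:
  Homogeneity Σp/(1+|i−j|), Energy Σp², Contrast Σ(i−j)²p, Dissimilarity
  Σ|i−j|p, Entropy −Σp·log₂p (bits, 0·log 0 = 0), Correlation
  Σ(i−μ)(j−μ)p/σ² from the (equal) marginals — NaN when σ = 0.
* **GLRLM**: maximal equal-level runs along the same 13 directions,
  aggregated into one matrix. Eleven standard emphases; RP divides by
  13 × n_voxels so it stays in (0, 1].
* **NGLDM**: per voxel, the dependence is the count of in-mask
  26-neighbors with exactly equal level (tolerance 0; boundary voxels
  simply have fewer neighbors, no renormalization). Coarseness, Contrast
  and Busyness use the Amadasun–King functional forms driven by the
  per-level summed |level − neighborhood mean|; Busyness is NaN on a
  single-level VOI, Contrast 0 with fewer than two levels, Coarseness is
  bounded by 1/ε with ε = 1e−8. These normalizations are this package's
  documented choice; published tools differ by large factors here (which
  is precisely why Busyness shows poor inter-observer ICC in clinical
  reports), so only internal consistency is claimed.
* **GLZLM**: 26-connected equal-level zones in 3D; same functional forms
  as the run-length indices, with ZP = zones per voxel.

Degenerate values (Correlation, Busyness on constant VOIs) are flagged NaN
and excluded pairwise downstream — never silently zeroed. All four
builders are tested for exact equality against independent nested-loop
enumerations on random small grids.

## Statistics

* **Pearson matrix**: pandas pairwise-complete correlation; zero-variance
  or mostly-missing (> 50% NaN) features are dropped with a logged warning.
* **Grouping**: greedy complete-linkage in the fixed table order of the 31
  indices — a group opens with the first unassigned feature and admits any
  feature whose |r| with *every* member exceeds 0.8; groups report
  mean ± SD of within-group pairwise |r| (singletons report "-").
* **Selection**: the first member of each group (overridable), minus
  representatives with |r| > 0.8 against SUVmax or MTV. The correlation
  stage pools the observer-1 feature rows of complete cases across the
  three methods.
* **Bland–Altman**: bias = mean difference, limits bias ± 1.96·SD (n−1).
* **Friedman**: rank closed form `12/(nk(k+1))·ΣR² − 3n(k+1)` with average
  ranks for ties and a χ²(k−1) reference; identical columns give statistic
  0, p = 1. No tie-correction factor is applied.
* **Wilcoxon signed-rank**: zero differences dropped; exact null for
  n ≤ 25 without ties, tie/continuity-corrected normal approximation
  otherwise; two-sided.
* **ICC**: ICC(2,1) — two-way random effects, absolute agreement, single
  measure — from the classical mean-squares closed form; NaN when all mean
  squares vanish (no between-subject variance). Landis–Koch labels:
  excellent > 0.8 (strict), great (0.6, 0.8], moderate (0.4, 0.6], low
  (0.2, 0.4], poor ≤ 0.2.
* No multiple-testing correction; raw p-values at α = 0.05.

## Study driver

`run_study` calibrates the adaptive law (if no coefficients are supplied),
generates the cohort, runs 3 methods × 2 observers per patient, extracts
features, and assembles the tables. A patient is analyzable under a method
only if *both* observers produced an eligible VOI; the statistical tables
use the complete-case subset analyzable under all three methods. Stage
errors are logged with patient/method/observer context and mark the
patient excluded rather than aborting. All randomness derives from the
single study seed; reruns are byte-identical.

Default problem sizes — 43 patients on 44 × 44 × 48 grids, 16 calibration
spheres, 200 rays — were chosen so the full study runs in a few seconds on
one CPU while keeping ≈ 29 complete cases for the agreement statistics.

## Known limitations

* The adaptive law is scanner- and blur-specific by construction; the
  shipped coefficients only apply to the phantom geometry they were
  calibrated on.
* The gradient method assumes a star-shaped lesion around the click;
  strongly concave lesions would need a surface-evolution approach.
* Inter-observer variability is modeled solely as click jitter; real
  observers also differ in cluster selection and in manual edits, so the
  synthetic ICCs for threshold methods sit at exactly 1 rather than the
  0.92–0.99 of clinical readings.
* Texture conventions (matrix aggregation over directions, NGLDM
  normalizations, log base) are documented but not benchmarked against any
  external tool's binaries.
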