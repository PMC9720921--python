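# Methods

## The index

For a hematoma with surface area *S* (mm²) and volume *V* (mm³) the package
computes the radii of the surface-area-equivalent and volume-equivalent
spheres, R1 = √(S/π)/2 and R2 = (3V/4π)^(1/3), and reports
HII = 100·R1/R2. The isoperimetric inequality guarantees HII ≥ 100 for any
solid in the continuum, with equality only for the ball; *n* disjoint
congruent balls give exactly 100·n^(1/6). The index is dimensionless: the
transformation (S, V) → (k²S, k³V) leaves it unchanged for any k > 0, which
the tests assert to machine precision. Reports round HII to one decimal;
machine output keeps full precision.

## Measurement pipeline

**Segmentation.** Acute clot is hyperdense (~40–100 HU) against brain
parenchyma (~0–40 HU). The segmenter keeps voxels with hu_low ≤ HU ≤ hu_high
(closed interval, defaults 40 and 100 — stated as a range without open/closed
notation in the clinical convention, so the inclusive reading of typical
threshold tools is used and is configurable), then restricts to one
26-connected component, chosen as the largest or as the one containing a
seed point. The slice-by-slice manual clean-up a rater would do is
represented by this component rule plus optional exclusion masks (e.g.
intraventricular blood), keeping the pipeline scriptable. No morphological
smoothing or hole-filling is applied by default: any such step changes S and
therefore the index.

**Surface extraction.** Marching cubes at level 0.5 on the binary field,
zero-padded by one layer so the surface always closes, with vertices scaled
by the voxel spacing into mm. One numerical choice matters and is worth
spelling out: an isosurface of the *raw* {0,1} field inherits the voxel
staircase, which inflates surface area by roughly 9% regardless of how fine
the grid is — the error is geometric, not statistical, so it never
converges away, and it propagates directly into an area-derived index. The
extractor therefore anti-aliases the indicator field with a Gaussian kernel
of 1.2 voxels (default, configurable; 0 disables) before extraction. The
kernel's physical width shrinks with the spacing, so measurements converge
to the continuum values under grid refinement (digitized r=20 mm sphere:
|HII−100| = 0.091, 0.078, 0.066 at 2, 1, 0.5 mm). On anisotropic grids the
kernel is anchored to the finest axis (sigma per axis scales as
min(spacing)/spacing), so 5 mm slices are not over-smoothed in physical
terms. Objects so small that the smoothed field never reaches the 0.5 level
fall back to the raw field rather than vanishing. Optional Taubin
(shrinkage-compensated) mesh smoothing is additionally available but off by
default; the per-case report records all smoothing settings, since any
smoothing choice shifts S. No claim is made of matching any particular GUI
tool's default smoothing bit-for-bit.

**Area and volume.** Surface area is the sum of triangle areas; volume is
the divergence-theorem (signed tetrahedra) sum over the same closed mesh, so
S and V always describe the same reconstructed object — mixing estimators
(e.g. mesh area with voxel-count volume) would bias the R1/R2 ratio. The
voxel-count volume is computed alongside as a consistency check; the two
agree within 2% at 0.5 mm isotropic sampling across the phantom suite.
Meshes are measured on the native grid; anisotropic voxels are handled by
physically scaled vertices, never by resampling. Orientation matrices are
not applied: S and V need spacing, not pose.

**Expansion rule.** Growth is classified as expansion iff
(V_followup − V_baseline)/V_baseline > 0.33 or the absolute increase
exceeds 12.5 mL, both strict. The comparison treats values equal to a
threshold up to float rounding (relative 1e-9) as *not* exceeding it, so
"exactly 33%" is no-expansion regardless of binary representation.

## Phantoms and what they do (not) show

Phantoms rasterize solids by the voxel-center-inside rule — simple,
unbiased at fine spacing, and trivially reimplementable as an oracle — and
embed them at 70 HU on a 30 HU background (defaults chosen to straddle the
40 HU threshold the way clot and parenchyma do), with optional seeded
Gaussian HU noise. Ground truth: closed forms for spheres and spheroids,
Legendre elliptic integrals for triaxial ellipsoids, and for lobulated
sphere-unions a brute-force oracle (the same union rasterized at 4× finer
spacing and measured by the same pipeline; 4× vs 8× refinement agrees
within 1%). Lobulated phantoms redraw lobe placements until the
sphere-overlap graph is connected, since the measured object is a single
hematoma; disconnected unions are covered analytically by the n^(1/6) law.
`resample_to_slices` emulates thick-slice clinical acquisition by slab
averaging along the slice axis.

Passing on phantoms shows the geometry and statistics are correct under
known ground truth. It does not show robustness to everything real head CT
contains — skull, ventricles, perihematomal edema, beam hardening, rater
disagreement over partial-volume boundary voxels — none of which the
generators model. One consequence is quantified here: on slab-averaged
volumes the 40 HU window edge lies below the 50 HU foreground/background
midpoint, so partial-volume voxels inflate the voxel volume by several
percent (midpoint thresholding is the unbiased reconstruction); on real
5 mm acquisitions this is exactly the boundary a rater corrects by hand,
and part of what inter-rater variability reflects.

## Cohort simulator

The simulator emulates a ~90-patient spontaneous-ICH cohort so the whole
statistics chain runs without patient data: age normal (64.2 ± 14.0 y),
binary risk factors Bernoulli (female 44%, alcohol 18%, smoking 18%,
hypertension 77%, diabetes 8%), onset-to-CT and baseline volume log-normal
(medians 3.0 h and 10.8 mL with matching IQRs), GCS a clipped discretized
normal with median 13 on 3–15, and HII = 100 + a log-normal excess (median
21.4, IQR 16.7–30.1) so the index respects its theoretical floor. Expansion
is Bernoulli(logistic(β·x)); the default effect is on HII only, β = 0.18
per index point (odds ratio ≈ 1.20), with the intercept −22.735 solved
once by Monte Carlo so that prevalence matches 36/93 ≈ 39% under the
default HII distribution. Every parameter is user-settable; no claim is
made of reproducing any particular cohort's per-patient data.

## Statistical choices

- **Baseline table**: Shapiro–Wilk at α = 0.05 per variable gates mean ± SD
  with t-test versus median (IQR) with Mann–Whitney U; both groups must pass
  for the parametric branch (the gate's grouping rule is not standardized;
  requiring both is the conservative choice). Groups below n = 3 (Shapiro
  undefined) take the nonparametric branch. Binary variables: chi-square,
  switching to Fisher's exact test when any expected cell count is < 5;
  zero-variance branches are flagged rather than raised.
- **Logistic regression**: maximum likelihood; 95% Wald CIs on the
  coefficient scale, exponentiated (the convention of mainstream clinical
  statistics software). Singular designs error naming the collinear
  columns; separation raises instead of reporting inflated ORs. Univariate
  p < 0.1 (strict) selects variables for the adjusted model, order-stable.
- **Hosmer–Lemeshow**: deciles of risk, χ² on g−2 df; groups with a
  degenerate expected count are merged into a neighbour and the used group
  count is returned. Calibration is itself tested by simulation: on
  correctly specified fits at n = 2000, the rejection rate at α = 0.05 is
  ~5% over 200 seeds.
- **ROC/Youden**: trapezoidal AUC over the empirical curve (equal to
  pair-counting with ties at ½ — asserted exhaustively against a brute-force
  oracle), DeLong 95% CI (standard nonparametric choice, no resampling
  seed), and the cutoff maximizing J = sens + spec − 1 with ties broken
  toward the lowest cutoff (deterministic, conservative toward
  sensitivity; rule: positive iff score ≥ cutoff).
- **Reliability**: ICC(1,1) from one-way random-effects ANOVA — the only
  ICC a one-way ANOVA defines — with the F test p-value. Rater-comparison
  location tests are run unpaired; a paired (signed-rank) reading of
  "rank-sum" is possible and would generally be more powerful, but unpaired
  is what the name states.

## Problem sizes

Default test and reproduction runs use r = 20 mm spheres at 2/1/0.5 mm
grids (up to ~270k foreground voxels), prolate ellipsoids with 10 mm minor
axes at 0.5 mm, a 5-lobe blob at 0.5 mm with its oracle at 0.125 mm, a
simulated cohort of n = 93 for the worked analysis, and n = 2000 with
100–200 seeds for parameter-recovery and calibration experiments — sizes at
which every analytic tolerance in the test suite is comfortably resolved.

## Known limitations

- Gantry tilt and oblique orientations are ignored (spacing-only geometry).
- No automatic ventricle detection or skull stripping; exclusion masks are
  user-supplied.
- HII is sensitive to the smoothing/anti-aliasing configuration; comparisons
  across datasets are only valid at identical settings (the report embeds
  them).
- The simulator draws covariates independently (no age–GCS–volume
  correlation structure); effect-recovery results should be read with that
  in mind.
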