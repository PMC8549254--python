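# Methods

## Geometry and conventions

All geometry lives in physical patient space, in millimetres, right-handed.
Slice index 0 is the most basal slice; indices increase toward the apex.
Slice normals point base-to-apex.  Contours are simple closed polygons
(closing edge implicit) and are orientation-normalised on load to positive
signed area in the slice's canonical in-plane basis — equivalently,
counterclockwise viewed along the normal.  With that single convention the
shoelace sum over a swept polygon (ED arc + reversed ES arc) is positive
exactly when the ES arc is displaced toward the contour interior, which is
what makes the septal sign convention (`+` toward the LV cavity, `−` toward
the RV) fall out of the arithmetic rather than a case analysis.

The long axis is the unit vector from the centroid of the six ED AV-plane
landmarks to the ED apical reference; AV-plane landmark displacements are
projected onto it (positive apically).  Projection makes AVPD insensitive
to in-plane landmark slippage between phases.

RV insertion points are snapped to the nearest contour vertex — no vertex
insertion — so arcs remain subsets of the delineated points; the error is
below one vertex spacing (3° on the default 120-gon).  The septal arc is
the shorter of the two arcs between the insertions, which is correct
whenever the septum spans less than half the circumference (anatomically it
does); a per-slice `septal_hint` point in the input file overrides the rule
for pathological shapes and is required to break an exact (antipodal) tie.

Planarity tolerance for contour vertices against their slice plane: 0.5 mm
(sub-voxel).

## Volumetrics

Slice summation: each delineated slice contributes area × (thickness +
gap).  No partial-volume weighting is applied to the basal slice — whether
a slice counts is decided by whether it carries a contour, mirroring how
delineation consensus handles the basal boundary.  Trabeculations and
papillary muscles are included in the cavity (the endocardial contour is
used as delineated).  Mass uses muscle density 1.05 g/ml on the ED
epicardial-minus-endocardial volume; solid apical slices (epicardium only)
contribute their full epicardial area to the wall.  EF is stored as a
fraction and rendered as percent.  Paradoxical ESV > EDV is representable
and flagged, not raised.

## Stroke-volume decomposition

- `SV_long` = mean AVPD × mean of the two largest ED epicardial areas among
  slices whose plane position lies in the closed interval swept by the AV
  plane (ED position to ES position along the long axis).  With exactly one
  in-band slice that area is used; with none, the most basal delineated
  slice's area — both flagged.  ED areas are used throughout.
- Radial terms: per slice, the region between the ED and ES epicardial
  arcs, closed by straight connectors at the (snapped) insertion points, is
  integrated with the shoelace formula.  Radial connectors contribute
  nothing to the sum, so the result equals the signed polar-area integral
  between the two arcs.  A swept region that self-intersects (e.g. part of
  the septum moving in while the rest moves out) is evaluated as the signed
  sum — partial cancellation is the intended physics — and flagged.
- Eligible slices for the radial sum have epicardial contours and both
  insertion points at both phases and lie strictly apical to the ES
  AV-plane position.  The apical truncation prevents the basal band already
  credited to `SV_long` from being counted twice.
- Percentages are taken against the slice-summation SV, not against the sum
  of the components; the shortfall/excess is reported as `residual_pct` and
  never redistributed.  On volume-conserving phantoms the residual stays
  within a few percent; it is not exactly zero because of basal-area
  averaging and slice discretization.
- When SV ≤ 0 (rigid or paradoxical ventricle) the millilitre values are
  still reported and all percentage fields are NaN, flagged.

A useful identity for interpretation: with an incompressible wall, the
ejected volume equals the total epicardial volume change, which is why all
three terms are epicardial quantities.

### Accuracy notes

Two second-order effects matter when validating against analytic truth:

- **Basal truncation.**  The radial sum covers whole slices apical to the
  ES AV plane, so up to half a slice spacing of ventricle length is dropped
  or added when the plane falls inside a slice.  At 4 mm spacing on an
  80 mm ventricle this is ≤ ~3 % of the radial terms; at clinical 8 mm
  spacing up to ~6 %.
- **Annular asymmetry.**  The area swept by an arc displaced inward by d is
  (2Rd − d²)/2 per radian, outward (2Rd + d²)/2, so negating a septal
  displacement negates the septal contribution only to first order in d/R
  (≈ 6 % at d = 2 mm, R = 33 mm).  Tests of the sign-flip property use a
  10 % tolerance for this reason.

## Synthetic phantoms

`generate_phantom` builds a cylinder or truncated half-ellipsoid: base
plane at z = 0, apex at −length, slice k centred at depth (k + ½) ×
spacing.  ES geometry: the AV plane (landmarks and basal band) moves
apically by `avpd_mm`; slices above the ES plane lose their ES contours
(the imaging plane now shows atrium); below it the epicardium is displaced
inward by a circumferential profile — `septal_inward_mm` (signed) over the
septal span, `lateral_inward_mm` on the free wall, cross-faded linearly
over a 10° transition so contours stay simple.  On the ellipsoid the
displacement is tapered in proportion to the local radius to keep apical
contours valid.

The ES endocardium is a circle whose area conserves total wall volume over
the shortened extent (incompressible myocardium, i.e. wall thickening as
the ventricle shortens).  This makes the analytic longitudinal + lateral +
septal swept volumes equal the true SV exactly for the cylinder and to
quadrature accuracy for the ellipsoid, so `PhantomTruth` is internally
consistent by construction rather than by fit.

Truth values: cylinder in closed form (the circumferential profile
integral is evaluated on a 4096-point grid, exact to ~1e−6); ellipsoid by
axial quadrature at 100× the slice resolution.  Defaults describe a
healthy-control-like ventricle: radius 33 mm (basal area ≈ 34 cm²), length
80 mm, wall 10 mm, AVPD 15.3 mm, septal span 120°, 10 slices (8 mm — a
typical clinical spacing) and 120 vertices per contour.  Noise (isotropic
in-plane vertex jitter and landmark jitter, clipped at 3σ) is off by
default: the default phantom is exact up to vertex discretization, and
noise is switched on explicitly where a test studies it.  Accuracy-focused
tests use 20 slices (4 mm) so that method error is not dominated by the
basal truncation above; the clinical 8 mm figure is exercised by the
volumetry checks.

What the phantoms do *not* emulate: myocardial fiber mechanics, wall
thickening heterogeneity, through-plane motion of oblique slices, true
trabeculated endocardium, and time-resolved motion (only ED and ES exist).
Passing phantom tests therefore demonstrates correctness of the geometric
computation, not segmentation robustness on real images.

## Synthetic cohorts

`generate_cohort` draws per-patient rows: responder class first, then
binary covariates per class (solving per-class exposure probabilities from
the requested marginal prevalence and covariate-outcome odds ratio), then
class-conditional normals for the regional measures, baseline LVESV
(truncated ≥ 50 ml), and an LVESV change drawn from class-conditional
truncated normals (responders ≤ −15 %, non-responders > −15 %) so that the
classifier recovers the class exactly.  QRS duration is drawn conditional
on the ≥ 150 ms flag; sex is encoded in a text column.  Defaults carry the
prevalences, odds ratios and per-class summaries of a 65-patient CRT
cohort (57 % responders).

Exact-count mode lays out a supplied cross-tabulation verbatim: class
sizes, per-covariate exposed counts, per-class missing counts (two
non-assessable dyssynchrony measurements), and the per-class sign pattern
of the septal contribution.  Covariates are assigned within class in
seed-permuted order so distinct covariates are not artificially collinear.
The continuous values around those counts remain synthetic: patient-level
means/SDs of the source cohort are emulated, not reproduced.

## Statistics

- Responder boundary inclusive: a reduction of exactly 15 % is a response.
  A septal contribution of exactly 0 % is classified with the positive
  group (negative is strictly < 0).
- Odds ratios: ad/(bc) with Woolf CIs using z = 1.96 (not t quantiles);
  Haldane–Anscombe 0.5 correction on any zero cell, flagged.
- Group comparisons: classic equal-variance Student t-tests; Pearson
  chi-squared without continuity correction; Fisher's exact test whenever
  any expected cell count is below 5.  Zero variance in both groups yields
  a flagged NaN rather than an error.
- Logistic screening: Newton-fitted maximum likelihood (statsmodels),
  convergence tolerance 1e−10, 100 iterations; Wald CIs.  Candidates with
  univariable p < 0.25 enter the joint model; multivariable predictors with
  p < 0.05 are listed as retained.  Separation is detected via failure or a
  diverging coefficient (|β| > 15) and reported as a non-finite OR.
- Sample size: smallest integer experimental-group n whose two-sided
  two-sample noncentral-t power meets the target, with a real-valued
  control group m·n in the power equation (allocation ratios from unequal
  cohorts are rarely integers; rounding is left to the caller).

## Known limitations

- Only ED and ES are analysed; abnormal septal motion occurring strictly
  between those phases (e.g. post-systolic shortening) is invisible to the
  decomposition.
- The basal-slice handling (no partial-volume weighting; in-band selection
  by slice-plane position) is a stated convention, not a fitted one;
  alternative conventions shift `SV_long` by up to one slice's worth of
  area × AVPD.
- The radial/longitudinal split is not exactly conservative; interpret
  `residual_pct` as a data-quality indicator.
- The cohort generator reproduces count structure and first/second moments
  per class; it does not model covariate-covariate dependence beyond what
  the outcome induces.
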