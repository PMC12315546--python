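# Methods

## Scope and data model

`icvnorm` analyses tabular brain-MRI volumetry: one row per 3D scan with
subject/visit/scan identifiers, age at visit, self-reported race (Asian,
Black, White), sex (Female, Male), an automatic segmentation-QC score in
[0, 1], and one column per ROI including total intracranial volume (ICV,
column name `"total intracranial"`).  Scan and subject tables are in
millilitres; cohort-level ICV parameters and summary tables are in litres.
Race and sex form a closed six-cell enumeration; free-text labels are
rejected at validation.

## Scan-to-subject aggregation

Scans with QC score **strictly** greater than 0.75 pass; if a visit has
more than three passing scans, the three with the highest scores are used
(ties at the cut break by scan id, lexicographically, for determinism —
the underlying rule gives no tie policy).  Volumes average per visit over
the retained scans, then per subject over visits with **equal weight per
visit**, so a subject's estimate does not depend on how many visits they
had; a pooled mode (all retained scans weighted equally) exists as a flag.
A visit whose scans all fail contributes nothing; a subject with no
passing scan in any visit is excluded and logged, never silently dropped.
Exact duplicate rows are treated as the same physical scan and
deduplicated on entry, which makes aggregation invariant to record
duplication; the top-3 rule is applied per visit (it is stated in the
context of a single MRI session).

## ICV correction

* **Division** (primary): `v' = (v / ICV) × mean(ICV)`, with the
  unweighted grand mean over the analysis cohort (a group-stratified mean
  would reintroduce group offsets by construction).  The ICV column maps
  to the constant mean, making a second application the identity.  Mean
  preservation is exact only when `v/ICV` and ICV are independent; on
  realistic cohorts it holds to well under 2%.
* **Residual**: `v' = v − β̂ (ICV − mean ICV)` with β̂ the
  least-absolute-deviation slope (median regression via statsmodels
  QuantReg) on a reference subset — robust, and coherent with the Laplace
  model downstream.  Degenerate (constant-ICV) references are an error.
* **Covariate**: a configuration token routes ICV into the trajectory fit
  as a centred linear nuisance term with one shared coefficient;
  predictions are then trajectories at the cohort-mean ICV.
* **Matching**: greedy 1:1 nearest-neighbour matching on ICV without
  replacement within a caliper, processing subjects in id order for
  determinism.  Volumes are never altered; the report carries the pair
  list and the post-matching standardized mean ICV difference.  Greedy
  matching pairs slightly fewer subjects than the optimal assignment
  (tests bound it at ≥ 80% of the Hungarian-solution cardinality) but
  balances means at least as well, because it never stretches to
  caliper-edge pairs.

Ventricles (and any configured ROI set) are modelled as log-volumes.
Division is applied to raw volumes first and the log taken afterwards
(the trajectory model consumes corrected volumes); a `log_before_division`
flag provides the alternative order for sensitivity analysis, since the
source analysis does not state one.

## Laplace location-scale spline model

At age *a*, volume follows a Laplace law with median μ(a) and scale b(a):

    log p(v; μ, b) = −ln(2b) − |v − μ| / b.

μ and ln b are B-splines sharing one clamped basis.  Defaults: cubic
degree, four control points anchored at ages 27/45/63/81, domain [18, 90].
With four control points and degree 3 there are no interior knots, so the
basis is the Bernstein basis on the domain and the anchor ages are
nominal; for lower degrees interior knots derive from the interior anchor
ages (degree 0 gives bin indicators centred on them).  The basis is a
nonnegative partition of unity on the domain, so constant shifts of the
data shift the coefficients exactly.

Parameterizing ln b (not b) guarantees positive scale for any coefficient
vector.  The fit maximizes the exact log-likelihood by gradient ascent:

* |x| is smoothed to √(x² + ε²) during optimization with ε = 10⁻⁶ of the
  robust volume spread, annealed down from 10⁻² in stages (continuation)
  — near-zero residuals otherwise create curvature ~1/ε that makes plain
  ascent crawl.  The reported log-likelihood is unsmoothed.
* Volumes are standardized internally (median 0, mean absolute deviation
  1) and the design matrix is whitened by QR so ascent runs in
  well-conditioned coordinates; both transforms are undone exactly.
* Location and scale blocks take separate line-searched steps (block
  gradient ascent with backtracking and step growth): the location block's
  curvature is ε-limited while the scale block's is O(1), and a joint step
  would move at the smaller of the two natural step sizes.
* Initialization is deterministic: least-squares spline for θ_μ, constant
  log-MAD of its residuals for θ_b.  No randomness anywhere in the fit.
* Convergence: per-datum gradient sup-norm < 10⁻⁶, or relative objective
  improvement < 10⁻⁸ sustained over consecutive accepted steps, or no
  step improving at line-search resolution; cap 5000 iterations, after
  which the fit is returned with `converged=False` and a warning.
  Accepted steps never decrease the objective.

With a degree-0 single-segment basis the model has the closed-form Laplace
MLE — sample median and mean absolute deviation about it — which the
optimizer reproduces to 10⁻⁶ relative error and the tests use as an
oracle.  The 95% band is reported as μ ± 3b; the exact multiple is
−ln 0.05 ≈ 2.9957, so nominal coverage of the 3b band is 1 − e⁻³ ≈ 0.9502.
The band describes population spread, not estimation uncertainty; no
standard errors on μ(a) are computed.

## Effect sizes

d(a) = 2|μ₁(a) − μ₂(a)| / (b₁(a) + b₂(a)), evaluated on a 1-year grid over
the common fit domain (the grid is a package choice; refinement tests show
1-year resolution determines d_max to ~1%).  Pairs default to the panel
layout — sexes within race, races within sex — with an all-pairs mode.
d_max is the grid maximum; the correction ratio d_max(raw)/d_max(corrected)
is reported per pair, with a zero corrected d_max flagged as an infinite
ratio rather than raised.  Comparing a log-scale fit with a raw-volume fit
is an error.

## Synthetic cohort generator

The generator emulates the real cohort's stated structure so that every
downstream stage is testable offline:

* Six demographic cells with the published sizes (total 5977), age
  means/SDs (truncated normal on [18, 90]; shape beyond two moments is
  not published) and ICV means/SDs in litres (normal, truncated at zero —
  never binding at these parameters).
* Per subject: 1–3 visits separated by 0.3–2 years, 1–4 scans per visit.
* Per ROI: volume = ICV × f(age), with f a spline in litres-per-litre of
  ICV from the same family the model fits (so parameter recovery is
  well-posed; a `misspecified` flag substitutes a piecewise-linear truth
  for robustness tests).  A single Laplace residual per subject provides
  between-subject spread (scale = `scale_frac` × age-specific median);
  per-scan Gaussian jitter is small relative to it (5% by default).
  ROIs in `log_normal_rois` (ventricles by default) apply the residual on
  the log scale, giving the right-skewed distributions those structures
  show.  Volumes outside (0, ICV) trigger a residual redraw; at the
  default scales the boundary sits ≥ ~6 Laplace scales away, so this
  never materially truncates the law.
* QC scores: passing scans draw 0.75 + 0.25·Beta(2,2); a planted fraction
  of subjects (default 23/6000, matching the excluded-subject count of the
  emulated cohort) draws all scans from 0.75·Beta(2,2) and therefore fails
  the strict filter, exercising subject exclusion with exact bookkeeping.
  No QC-score distribution is published; the Beta forms are a package
  choice.
* Only the ICV laws, cell sizes, age moments and exclusion fraction are
  calibrated to published values.  Per-ROI trajectory shapes and scales
  are plausible adult values (e.g. whole brain ~0.80 → 0.66 L/L of ICV
  across adulthood, ventricles growing ~0.008 → 0.034 with log-scale
  spread 0.4) — no per-ROI group medians are published for this cohort,
  so green tests establish correct mechanics under the stated ICV-driven
  structure, not per-ROI empirical accuracy.

Everything is deterministic given the spec's seed; two generations from
identical specs are byte-identical.

## What the tests do and do not establish

Cohort-level numbers are reproduced exactly where their inputs are
published: the nine in-text ICV ratios and the global 1.12 male/female
ratio follow from the printed cell means and counts, and the 95% band
multiple from the Laplace law.  Parameter recovery is verified on data
simulated from known coefficients (location within 2%, scale within 10% at
ages 30/50/70 with n = 4000) — simulated directly from the Laplace spline
law, because a cohort with realistic ICV spread has a Gaussian×ICV +
Laplace marginal whose scale is not the generative b.  The
normalization claims are verified qualitatively: on cohorts whose group
differences are purely head-size driven, division correction shrinks the
within-race sex d_max by factors well above 2 and leaves residual
volume–ICV correlation below 0.05.  Figure-level numbers of the emulated
study (per-ROI d_max values, reduction factors between 2 and 8) depend on
the unpublished per-ROI data and are not asserted.

## Known limitations

* Gradient ascent is first-order; fits with near-degenerate designs (ages
  spanning a narrow range) converge to the stationary point but may need
  thousands of iterations.  At very small group sizes (tens of subjects)
  the scale spline is weakly constrained near the domain edges and d_max
  over the full [18, 90] grid can be edge-inflated; this reflects the
  model family, not the optimizer.
* The residual/covariate/matching schemes follow the standard forms from
  the normalization-comparison literature; their exact variants in the
  emulated study's supplement (reference group, matching ratio) are not
  public.
* The generator models scanner effects only as scalar jitter and contains
  no disease cohorts.
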