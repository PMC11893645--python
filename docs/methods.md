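# Methods

This note documents the models, estimators and numerical choices behind the
package, and what the synthetic cohort does and does not emulate.

## Growth-spurt alignment

Each child's maturity clock is set by **PGA90%**, the age at which standing
height first reaches 90 % of adult height. Adult height is the final-visit
standing height of a child whose final inter-visit velocity is below
1 cm/yr; the final height (not the maximum) is used because the criterion
already bounds residual growth and a maximum is upward-biased under
measurement noise.

To locate the 90 % crossing on noisy serial heights, the height sequence is
first made monotone by isotonic regression (pool-adjacent-violators), then
interpolated with a shape-preserving piecewise cubic (PCHIP). The monotone
fit makes the *first* crossing unique; it is solved by bisection to 1e-8 yr.
If the child is already above the target at the first visit, or never
reaches it, the subject is flagged rather than extrapolated. Subjects
failing the maturity criterion are excluded from all multiplier and
velocity estimation: those quantities are only defined against a known
adult state.

## Spine reconstruction

All heights are floor-referenced centimetres; radiographic offsets are
signed, upward-positive, so `landmark height + offset` is the height of the
bony structure. S1 height uses the pelvic landmark recorded for the visit,
falling back to the fixed priority symphysis > iliac crest > ASIS when none
is recorded (reproducibility over case-by-case judgement).

The percent-C1-S1 method's ratio defaults to the value estimated from the
cohort itself (pooled per-visit median of direct T1–S1 over the approximate
C1–S1 span); a fixed ratio (e.g. 0.762) can be passed instead. The optional
EAM→C1 offset (+1.7 cm default) is **off** by default: the operative
definition of the approximate C1 is simply stature minus head height.

The body-regression method carries a units convention tag (`raw_cm` by
default) inside the fitted `BetaFit`; the fit and the inversion must use
the same convention, and mixing raises an error. The package makes no claim
about the scaling under which a proportionality constant near 1.378 arises —
fitted on raw centimetres, body height over T1–S1 gives β ≈ 3.8, and
correctness of the method is guaranteed by self-consistency (fit and
inversion on the same convention), not by any particular constant.
Note that multipliers computed from this method reduce to standing-height
multipliers (β cancels in the adult/current ratio), which is why its
multiplier column differs visibly from the direct column.

## Multipliers and their table

Multiplier = adult T1–S1 / current T1–S1, with adult T1–S1 the mean of the
subject's estimates at timing ≥ +4 yr (averaging reduces the noise injected
into every one of the subject's multipliers by a single final visit). The
table bins observations on the grid −4.0 .. +4.5 yr in half-open bins
[t−0.25, t+0.25), clamps cell means at ≥ 1.000, and leaves empty bins
missing — they are never silently interpolated. Table lookups interpolate
linearly between grid cells, return exactly 1.0 past the grid, and refuse
timings before −4 (extrapolation into early childhood is not supported).

Adult-spine prediction returns the two predictions from the percent-C1-S1
and body-height reference columns, ordered by value (the columns cross near
timing −0.5, so neither is uniformly the lower bound), with the midpoint as
the point estimate.

## Timing versus age as a predictor

Multiplier-vs-predictor curves are cubic smoothing splines with the
smoothing parameter selected by generalized cross-validation
(`scipy.interpolate.make_smoothing_spline`). Observations sharing an
abscissa are merged into one weighted point before fitting; residuals are
reported per original observation. Because the penalty acts on curvature,
even a noiseless cubic truth is reproduced only to ~1e-6 — the smoother
shrinks, it does not interpolate.

The timing model pools sexes (timing alignment removes the sex difference);
the age models are fitted per sex and their residuals pooled. The
comparison statistic is a paired two-sided Wilcoxon signed-rank test on
per-visit absolute residuals (AVRs). Since the two models use different
predictors, this is an exploratory comparison, not a formal model test —
the report says so in its `caveat` field.

## Phase velocities and segmental rates

Phase knots are fixed at −2, +2 and +4 yr from PGA90%, phases half-open on
the right. Velocity is estimated per subject by OLS within each phase
(≥ 2 visits required), then summarised across subjects as mean, SEM and SD
— the per-subject-then-summarise design is what gives both dispersion
measures meaning. Negative slopes are reported as estimated; nothing is
clamped on the analysis side.

Segmental rates convert a phase velocity v (cm/yr) to
`10·v·0.63/12` mm/segment/yr thoracic and `10·v·0.27/5` lumbar, rounded
half-away-from-zero to 0.1 mm. With childhood velocities of 1.55 (girls)
and 1.14 (boys) cm/yr this yields 0.8 and 0.6 mm/segment/yr.

## The synthetic cohort

The generator emulates the statistical structure the analysis assumes, at
the study scale of 35 girls and 19 boys:

* **Subject-level truth.** PGA90% age and adult height are truncated
  normals over the published ranges (girls 9.7–13.4 yr mean 11.3, boys
  11.7–14.3 mean 13.0; heights 151–175 cm mean 163.4 and 169–183.9 cm mean
  177) with sd = range/4 — the ranges are asymmetric, so the truncated
  means sit slightly off the nominal centres (≈ +0.07 yr for girls). Adult
  T1–S1 is 27 % of adult height; each child has their own T1–S1/C1–S1
  ratio (truncated normal 0.762 ± 0.0176), head height (13.0 ± 0.8 cm,
  constant over time — cranial height matures early), and radiographic
  offsets, drawn once per subject.
* **Trajectories.** Standing height follows a monotone PCHIP fraction
  curve anchored at (−4, 0.79), (−2, 0.85), (0, 0.90), (+4.25, 1.0);
  the T1–S1 fraction curve's anchors are the reciprocal of the reference
  body-height multiplier column, so multiplier recovery closes on the
  published table. A second mode (`trajectory_mode="piecewise_linear"`)
  builds T1–S1 exactly from the phase velocities so velocity estimators are
  tested against a truth free of interpolation error; its mature-phase male
  slope (−0.12, estimation noise in origin) is clamped to 0 to keep the
  truth monotone. Below the first anchor the fraction curves continue
  linearly at the childhood slope; above the last they are exactly 1.
* **Geometry.** S1 height is placed so every reconstruction identity holds
  exactly at zero noise: C1 (≈ stature − head height) sits one subject
  C1–S1 span above S1, T1 one T1–S1 span above S1, pelvic landmarks at
  subject-specific gaps around S1. Pelvic width is a per-subject constant
  fraction of T1–S1 (0.60 ± 0.03) — without between-child variation in
  pelvic proportions a width-calibrated prediction band would be
  unrealistically narrow.
* **Visits and noise.** Visits run from 6 yr before to 5.5 yr after the
  true PGA90% (clipped at age 3), annually, biannually, or mixed
  (biannual within ±2 yr of the spurt; the default). Independent Gaussian
  noise is added per measurement: 0.3 cm anthropometric, 0.2 cm
  radiographic — the source cohort reports no error magnitudes, so these
  are this package's own declared defaults. A single seed fans out into
  per-subject substreams keyed by (sex, index), so growing the cohort never
  reshuffles existing subjects.

What the generator does **not** emulate: secular trend, the historical
mid-series switch of pelvic landmark protocols, sitting-height-specific
error structure, missing-data patterns of real archives, or any
departure of real growth from the smooth fraction curves. Passing recovery
tests therefore demonstrates that the estimators are correct and
well-calibrated under the stated model — not that the model captures every
feature of real serial measurements.

A separate unit-agnostic generator produces `(x, β·x + ε)` pairs for
testing the regression-through-origin estimator in isolation, since a
single proportionality constant cannot be embedded consistently in the
anatomical cohort.

## Problem sizes and determinism

Default analyses use the study-scale cohort (54 subjects, ~900 visits) and
run in seconds; Monte-Carlo distribution checks use 10 000 subject draws,
and estimator-bias checks 200 subjects. Every random quantity flows from an
explicit integer seed; identical configuration and seed give byte-identical
output tables.

## Known limitations

* The maturity criterion applied to a short (0.5 yr) final interval is
  noise-sensitive: with default noise ~10–15 % of synthetic subjects fail
  it and are excluded, mildly reducing the effective n.
* Terminal- and mature-phase velocities rest on 2–3 visits per subject, so
  their SEMs (~0.12–0.21 cm/yr at study scale) dwarf those of the
  childhood and spurt phases; treat those cells as indicative.
* The external pelvic-width check requires user-supplied model
  coefficients; the package deliberately embeds none, and the shipped
  calibration helper is for synthetic-truth studies only.
* Multipliers below timing −4 are refused rather than extrapolated; the
  early-childhood spine is outside the supported range.
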