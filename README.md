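# spinegrowth

Longitudinal analysis of spinal height growth in children: reconstruct
T1–S1 spine height from anthropometric and radiographic landmark
measurements, align children on the timing of their adolescent growth
spurt, and derive growth-remaining multipliers and phase-wise growth
velocities that predict adult spine height.

Intended for biostatisticians and pediatric-orthopaedics researchers who
work with serial growth measurements — in particular for planning
growth-modulating spinal deformity treatment, where the question "how much
spine growth is left?" is the clinically decisive one.

## The model

Children enter their adolescent growth spurt at different ages, so averaging
by chronological age blurs the spurt. The analysis instead aligns every child
on **PGA90%** — the age at which standing height first reaches 90 % of adult
height, a robust surrogate for the timing of peak height velocity. Growth
completion is declared when standing height increases by < 1 cm/yr over the
final inter-visit interval.

Per visit, T1–S1 spine height is reconstructed three ways from
floor-referenced landmark heights plus signed radiographic offsets
(`landmark height + offset = structure height`):

1. **direct** — `(sternal notch + offset to T1) − (pelvic landmark + offset to S1)`;
2. **percent C1-S1** — C1 ≈ stature − head height; T1–S1 taken as the cohort
   median fraction (~76.2 %) of the C1–S1 span;
3. **body regression** — spine measure from standing height through a
   proportionality constant fitted by regression through the origin,
   `body = β·spine + ε`, `β̂ = Σxy/Σx²`.

For each visit the **multiplier** is adult T1–S1 divided by current T1–S1
(its reciprocal is the fraction of mature spine height attained; the spine is
~87 % of adult height at PGA90%, versus 90 % for stature). Multipliers are
binned on a half-year timing grid from −4 to +4.5 yr; T1–S1 growth velocity
is estimated per subject by OLS within four phases (childhood < −2 yr, spurt
−2..2, terminal 2..4, mature ≥ 4 yr from PGA90%) and summarised across
subjects. Segment-level rates spread each velocity over the thoracic (63 %,
12 segments) and lumbar (27 %, 5 segments) shares of T1–S1.

Because the original cohort data cannot be redistributed, the package ships a
calibrated synthetic cohort generator (`spinegrowth.simulate`) that emulates
the measurement schema, visit schedule, sex-specific spurt timing and adult
height distributions, with ground truth returned for parameter-recovery
testing.

## Worked example

Run the numbered analysis scripts from the repository root:

```bash
python analysis/01_simulate_cohort.py
python analysis/02_assess_maturity.py
python analysis/03_reconstruct_spine.py
python analysis/04_multipliers.py
python analysis/05_velocities.py
python analysis/06_validate_pelvic.py
```

Output of step 04 on the default seed-1 cohort:

```
multiplier at timing -2.0 yr -> direct: 1.273 | c1s1_fraction: 1.275 | body_regression: 1.175
multiplier at timing +0.0 yr -> direct: 1.146 | c1s1_fraction: 1.147 | body_regression: 1.110
multiplier at timing +2.0 yr -> direct: 1.042 | c1s1_fraction: 1.041 | body_regression: 1.054
median AVR vs timing 0.0014 < pooled median AVR vs age 0.0114 (p = 2.8e-120)
```

A multiplier of 1.273 two years before the spurt peak means the spine will
grow another 27.3 % of its current length; the residual comparison (paired
Wilcoxon on absolute spline residuals) shows spurt timing predicts the
multiplier far better than chronological age. Step 05 prints the phase
velocities (girls ~1.5 cm/yr childhood rising to ~2 cm/yr in the spurt on
this cohort) and the per-segment arithmetic (0.8 mm/segment/yr for
preadolescent girls).

To predict an individual child's adult spine height from the published
multiplier table:

```bash
spinegrowth predict --t1s1-cm 38.0 --timing-yr 0.0
# {"point_cm": 43.85, "lower_cm": 43.62, "upper_cm": 44.08, ...}
```

The same steps are available as one call (`spinegrowth run --seed 1
--out-dir out/`) or programmatically via `spinegrowth.pipeline.run_pipeline`.

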