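"""Multipliers, multiplier tables, spline/AVR comparison, phase velocities."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spinegrowth.analysis import (avr_compare, build_multiplier_table,
                                  compute_multipliers, fit_multiplier_spline,
                                  interpolate_multiplier,
                                  phase_velocity_summary, predict_adult_spine,
                                  segmental_rates, subject_phase_slopes)
from spinegrowth.errors import AnalysisError
from spinegrowth.pipeline import assess_cohort, build_estimate_table
from spinegrowth.reference import reference_multiplier_table
from spinegrowth.simulate import (DEFAULT_SPINE_ANCHORS, GeneratorConfig,
                                  generate_cohort)


def _obs_df(rows):
    return pd.DataFrame(rows, columns=["subject_id", "sex", "age", "timing",
                                       "method", "t1s1"])


class TestComputeMultipliers:
    def test_ratio_arithmetic(self):
        df = _obs_df([
            ("s1", "F", 11.0, 0.0, "direct", 38.324),
            ("s1", "F", 16.0, 5.0, "direct", 44.0),
        ])
        obs = compute_multipliers(df)
        at_peak = obs[obs["timing"] == 0.0]["multiplier"].iloc[0]
        assert round(at_peak, 3) == 1.148  # 44.0 / 38.324

    def test_mature_visit_has_multiplier_one(self):
        df = _obs_df([("s1", "F", 16.0, 5.0, "direct", 44.0)])
        obs = compute_multipliers(df)
        assert obs["multiplier"].iloc[0] == pytest.approx(1.0)

    def test_subject_without_mature_visits_skipped_with_warning(self):
        df = _obs_df([
            ("s1", "F", 11.0, 0.0, "direct", 38.0),
            ("s2", "F", 16.0, 5.0, "direct", 44.0),
        ])
        with pytest.warns(UserWarning, match="s1"):
            obs = compute_multipliers(df)
        assert set(obs["subject_id"]) == {"s2"}

    def test_noise_free_multiplier_two_years_before_peak(
            self, noise_free_cohort):
        _, cohort, _ = noise_free_cohort
        assessments = assess_cohort(cohort)
        estimates, _, _ = build_estimate_table(cohort, assessments,
                                               methods=("direct",))
        obs = compute_multipliers(estimates)
        near = obs[np.isclose(obs["timing"], -2.0, atol=1e-6)]
        assert len(near) > 0
        assert near["multiplier"].to_numpy() == pytest.approx(1.274, abs=0.002)

    def test_reciprocal_identity(self, default_estimates):
        _, estimates, _, _ = default_estimates
        obs = compute_multipliers(estimates)
        percent = 100.0 / obs["multiplier"]
        assert np.allclose(percent * obs["multiplier"], 100.0)


class TestMultiplierTable:
    def test_default_cohort_cell_values(self, default_estimates):
        _, estimates, _, _ = default_estimates
        obs = compute_multipliers(estimates[estimates["method"] == "direct"])
        table = build_multiplier_table(obs)
        assert table.loc[-2.0, ("direct", "mean")] == pytest.approx(1.274, abs=0.02)
        assert table.loc[0.0, ("direct", "mean")] == pytest.approx(1.148, abs=0.02)

    def test_all_unit_observations_give_unit_cells(self):
        df = _obs_df([("s1", "F", 10 + t, t, "direct", 40.0)
                      for t in np.arange(-4, 5.6, 0.5)])
        obs = compute_multipliers(df)
        table = build_multiplier_table(obs)
        means = table[("direct", "mean")].dropna()
        assert np.allclose(means, 1.0)

    def test_half_open_bin_convention(self):
        # an observation exactly at -0.25 belongs to the 0.0 bin, not -0.5
        df = _obs_df([
            ("s1", "F", 10.0, -0.25, "direct", 40.0),
            ("s1", "F", 16.0, 5.0, "direct", 44.0),
        ])
        table = build_multiplier_table(compute_multipliers(df))
        assert table.loc[0.0, ("direct", "n")] == 1
        assert np.isnan(table.loc[-0.5, ("direct", "n")])

    def test_columns_nonincreasing_on_default_cohort(self, default_estimates):
        _, estimates, _, _ = default_estimates
        obs = compute_multipliers(estimates)
        table = build_multiplier_table(obs)
        for method in ("direct", "c1s1_fraction", "body_regression"):
            means = table[(method, "mean")].dropna().to_numpy()
            assert np.all(np.diff(means) <= 0.01)

    def test_noise_free_closure_recovers_fraction_anchors(self):
        # biannual schedule so every half-year grid bin is populated
        cfg = GeneratorConfig(seed=2, noise_sd_anthro=0.0, noise_sd_radio=0.0,
                              c1s1_ratio_sd=0.0, visit_schedule="biannual")
        cohort, _ = generate_cohort(cfg)
        assessments = assess_cohort(cohort)
        estimates, _, _ = build_estimate_table(cohort, assessments,
                                               methods=("direct",))
        table = build_multiplier_table(compute_multipliers(estimates))
        anchors = dict(DEFAULT_SPINE_ANCHORS)
        for t in np.arange(-4.0, 4.51, 0.5):
            cell = table.loc[t, ("direct", "mean")]
            assert abs(1.0 / cell - anchors[t]) < 0.01


class TestReferenceTable:
    def test_reference_constants_satisfy_table_invariants(self):
        table = reference_multiplier_table()
        assert len(table) == 18
        for col in table.columns:
            assert np.all(np.diff(table[col].to_numpy()) <= 0)
            assert table[col].iloc[-1] == pytest.approx(1.0)

    def test_percent_c1s1_column_steps_uniformly(self):
        table = reference_multiplier_table()
        col = table["percent_c1s1"].loc[-4.0:3.5].to_numpy()
        assert np.allclose(np.diff(col), -0.022)


class TestInterpolation:
    def test_exact_at_grid_points(self):
        table = reference_multiplier_table()
        assert interpolate_multiplier(table["body_height"], 0.0) == 1.148

    def test_midpoint_between_grid_points(self):
        table = reference_multiplier_table()
        got = interpolate_multiplier(table["body_height"], 0.25)
        assert got == pytest.approx((1.148 + 1.117) / 2)

    def test_past_grid_returns_unity(self):
        table = reference_multiplier_table()
        assert interpolate_multiplier(table["body_height"], 5.0) == 1.0

    def test_before_grid_refused(self):
        table = reference_multiplier_table()
        with pytest.raises(AnalysisError) as err:
            interpolate_multiplier(table["body_height"], -4.5)
        assert err.value.code == "OUT_OF_RANGE"

    def test_missing_cells_never_silently_interpolated(self):
        col = pd.Series([1.3, np.nan, 1.1],
                        index=pd.Index([-1.0, 0.0, 1.0], name="timing"))
        with pytest.raises(AnalysisError) as err:
            interpolate_multiplier(col, -0.5)
        assert err.value.code == "MISSING_CELL"


class TestPrediction:
    def test_bounds_at_peak_ordered_by_value(self):
        table = reference_multiplier_table()
        pred = predict_adult_spine(38.0, 0.0, table)
        # percent-C1-S1 column (1.160) exceeds body-height (1.148) at the peak
        assert pred.lower == pytest.approx(38.0 * 1.148)
        assert pred.upper == pytest.approx(38.0 * 1.160)
        assert pred.lower_method == "body_height"
        assert pred.point == pytest.approx((pred.lower + pred.upper) / 2)

    def test_bounds_two_years_before_peak(self):
        table = reference_multiplier_table()
        pred = predict_adult_spine(30.0, -2.0, table)
        assert {round(pred.lower, 2), round(pred.upper, 2)} == {37.44, 38.22}

    @pytest.mark.parametrize("timing", [4.5, 5.0, 10.0])
    def test_identity_at_maturity(self, timing):
        table = reference_multiplier_table()
        pred = predict_adult_spine(41.3, timing, table)
        assert pred.point == pred.lower == pred.upper == pytest.approx(41.3)


class TestSplineAndAvr:
    def test_noiseless_cubic_essentially_interpolated(self):
        x = np.linspace(-4, 4, 60)
        y = 0.001 * x ** 3 - 0.02 * x + 1.1
        df = pd.DataFrame({"subject_id": "s", "sex": "F", "age": x + 11,
                           "timing": x, "method": "m", "multiplier": y})
        fit = fit_multiplier_spline(df, predictor="timing")
        assert np.abs(fit.residuals).max() < 5e-6

    def test_outlier_shrunk_by_smoothing(self):
        rng = np.random.default_rng(0)
        x = np.linspace(-4, 4, 80)
        y = 1.2 - 0.02 * x + rng.normal(0, 0.005, x.size)
        y[40] += 0.5
        df = pd.DataFrame({"subject_id": "s", "sex": "F", "age": x + 11,
                           "timing": x, "method": "m", "multiplier": y})
        fit = fit_multiplier_spline(df, predictor="timing")
        assert abs(fit.fitted[40] - (1.2 - 0.02 * x[40])) < 0.5

    def test_too_few_points_refused(self):
        df = pd.DataFrame({"subject_id": "s", "sex": "F", "age": [1, 2],
                           "timing": [0, 1], "method": "m",
                           "multiplier": [1.2, 1.1]})
        with pytest.raises(AnalysisError):
            fit_multiplier_spline(df)

    def test_identical_residuals_give_p_one(self):
        r = pd.Series(np.linspace(-0.1, 0.1, 30))
        cmp = avr_compare(r, r.copy())
        assert cmp.p_value == 1.0
        assert cmp.median_avr_timing == cmp.pooled_median_avr_age

    def test_uniformly_smaller_avrs_highly_significant(self):
        rng = np.random.default_rng(1)
        age = pd.Series(rng.normal(0, 1, 100))
        timing = age / 2
        cmp = avr_compare(timing, age)
        assert cmp.p_value < 1e-4
        assert cmp.median_avr_timing < cmp.pooled_median_avr_age

    def test_unpaired_series_refused(self):
        with pytest.raises(AnalysisError) as err:
            avr_compare(pd.Series([1.0, 2.0]), pd.Series([1.0, 2.0, 3.0]))
        assert err.value.code == "PAIRING"

    def test_timing_beats_age_on_default_cohort(self, default_estimates):
        from spinegrowth.pipeline import avr_report
        _, estimates, _, _ = default_estimates
        obs = compute_multipliers(estimates)
        report = avr_report(obs)
        assert report["median_avr_timing"] < report["pooled_median_avr_age"]
        assert report["p_value"] < 1e-4


class TestPhaseVelocities:
    def test_two_point_childhood_slope(self):
        df = _obs_df([
            ("s1", "F", 8.0, -3.0, "direct", 30.0),
            ("s1", "F", 8.5, -2.5, "direct", 30.775),
        ])
        slopes = subject_phase_slopes(df)
        assert len(slopes) == 1
        assert slopes["phase"].iloc[0] == "childhood"
        assert slopes["slope"].iloc[0] == pytest.approx(1.55)

    def test_single_visit_in_phase_emits_nothing(self):
        df = _obs_df([("s1", "F", 8.0, -3.0, "direct", 30.0),
                      ("s1", "F", 11.0, 0.0, "direct", 35.0)])
        slopes = subject_phase_slopes(df)
        assert slopes.empty or "childhood" not in set(slopes["phase"])

    def test_noise_free_piecewise_cohort_recovers_slopes_exactly(self):
        cfg = GeneratorConfig(seed=4, trajectory_mode="piecewise_linear",
                              noise_sd_anthro=0.0, noise_sd_radio=0.0,
                              c1s1_ratio_sd=0.0)
        cohort, _ = generate_cohort(cfg)
        assessments = assess_cohort(cohort)
        estimates, _, _ = build_estimate_table(cohort, assessments,
                                               methods=("direct",))
        summary = phase_velocity_summary(subject_phase_slopes(estimates))
        by = summary.set_index(["sex", "phase"])["mean"]
        for sex, (vc, vs, vt, vm) in cfg.phase_velocities.items():
            assert by[(sex, "childhood")] == pytest.approx(vc, abs=1e-9)
            assert by[(sex, "spurt")] == pytest.approx(vs, abs=1e-9)
            assert by[(sex, "terminal")] == pytest.approx(vt, abs=1e-9)
            assert by[(sex, "mature")] == pytest.approx(max(0.0, vm), abs=1e-9)

    def test_summary_arithmetic(self):
        slopes = pd.DataFrame({
            "subject_id": ["a", "b"], "sex": ["F", "F"],
            "phase": ["spurt", "spurt"], "slope": [1.5, 1.6],
            "n_visits": [4, 4],
        })
        out = phase_velocity_summary(slopes)
        assert out["mean"].iloc[0] == pytest.approx(1.55)
        assert out["sd"].iloc[0] == pytest.approx(0.0707, abs=1e-4)
        assert out["sem"].iloc[0] == pytest.approx(0.05)

    def test_estimator_unbiased_on_noisy_piecewise_truth(self):
        # Monte-Carlo: slope estimates scatter around the configured truth
        cfg = GeneratorConfig(seed=8, n_female=200, n_male=0,
                              trajectory_mode="piecewise_linear")
        cohort, _ = generate_cohort(cfg)
        assessments = assess_cohort(cohort)
        estimates, _, _ = build_estimate_table(cohort, assessments,
                                               methods=("direct",))
        summary = phase_velocity_summary(subject_phase_slopes(estimates))
        by = summary.set_index(["sex", "phase"])
        for phase, truth in (("childhood", 1.55), ("spurt", 1.75),
                             ("terminal", 0.9), ("mature", 0.0474)):
            row = by.loc[("F", phase)]
            assert abs(row["mean"] - truth) < 3 * row["sem"] + 1e-9

    def test_negative_slopes_are_reportable(self):
        df = _obs_df([("s1", "M", 17.0, 4.5, "direct", 44.0),
                      ("s1", "M", 18.0, 5.5, "direct", 43.8)])
        slopes = subject_phase_slopes(df)
        assert slopes["slope"].iloc[0] == pytest.approx(-0.2)


class TestSegmentalRates:
    def test_preadolescent_rates_match_published_values(self):
        vel = pd.DataFrame({"sex": ["F", "M"], "phase": ["childhood"] * 2,
                            "mean": [1.55, 1.14]})
        seg = segmental_rates(vel)
        rates = seg.rates.set_index("sex")
        assert rates.loc["F", "thoracic_mm_per_segment_yr"] == 0.8
        assert rates.loc["M", "thoracic_mm_per_segment_yr"] == 0.6
        assert rates.loc["F", "lumbar_mm_per_segment_yr"] == 0.8
        assert rates.loc["M", "lumbar_mm_per_segment_yr"] == 0.6

    def test_zero_velocity(self):
        vel = pd.DataFrame({"sex": ["F"], "phase": ["mature"], "mean": [0.0]})
        seg = segmental_rates(vel)
        assert seg.rates["thoracic_mm_per_segment_yr"].iloc[0] == 0.0


@settings(max_examples=30, deadline=None)
@given(st.floats(min_value=20.0, max_value=60.0),
       st.floats(min_value=-4.0, max_value=6.0))
def test_prediction_bounds_bracket_point(current, timing):
    table = reference_multiplier_table()
    pred = predict_adult_spine(current, timing, table)
    assert pred.lower <= pred.point <= pred.upper
    assert pred.lower >= current * 0.99
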