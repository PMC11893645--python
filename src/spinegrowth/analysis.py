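"""Growth-remaining multipliers, phase velocities and segmental rates.

The results engine.  Observations live in tidy :class:`pandas.DataFrame`
objects with one row per (subject, visit, method):

======================  =======================================================
column                  meaning
======================  =======================================================
``subject_id``          child identifier
``sex``                 "F" / "M"
``age``                 chronological age, yr
``timing``              age minus the subject's PGA90% age, yr
``method``              reconstruction method name
``t1s1``                reconstructed spine height, cm
``multiplier``          adult T1-S1 / current T1-S1 (added downstream)
======================  =======================================================

A multiplier of m means the spine will reach m times its current length at
maturity; 100/m is the percent of adult spine height already attained.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import make_smoothing_spline
from scipy.stats import wilcoxon

from .errors import AnalysisError
from .reference import (LUMBAR_FRACTION, N_LUMBAR, N_THORACIC, PHASE_ORDER,
                        PHASES, THORACIC_FRACTION)

#: Timing grid of the multiplier table, yr relative to PGA90%.
DEFAULT_GRID = np.arange(-4.0, 4.51, 0.5)
#: Half-width of each grid bin; bins are half-open [t - 0.25, t + 0.25).
BIN_HALFWIDTH = 0.25
#: Timing from which a subject's spine is treated as mature.
MATURE_TIMING = 4.0


def round_half_away(x: float, decimals: int = 0) -> float:
    """Round half away from zero (the convention of the reported tables)."""
    factor = 10.0 ** decimals
    return math.copysign(math.floor(abs(x) * factor + 0.5) / factor, x)


# -- multipliers -----------------------------------------------------------

def adult_t1s1_by_subject(estimates: pd.DataFrame,
                          mature_timing: float = MATURE_TIMING) -> pd.Series:
    """Adult T1-S1 per (subject, method): mean of estimates at timing >= 4.

    Averaging the mature-phase visits rather than taking a single final visit
    reduces the noise carried into every one of the subject's multipliers.
    """
    mature = estimates[estimates["timing"] >= mature_timing]
    return mature.groupby(["subject_id", "method"])["t1s1"].mean()


def compute_multipliers(estimates: pd.DataFrame,
                        mature_timing: float = MATURE_TIMING) -> pd.DataFrame:
    """One multiplier observation per visit per method.

    ``multiplier = adult T1-S1 / current T1-S1`` with the adult value taken
    as the subject's mean estimate at timing >= ``mature_timing`` under the
    same method.  Subjects with no mature-phase visit are skipped with a
    warning.
    """
    adult = adult_t1s1_by_subject(estimates, mature_timing)
    merged = estimates.merge(
        adult.rename("adult_t1s1"), left_on=["subject_id", "method"],
        right_index=True, how="left",
    )
    missing = merged["adult_t1s1"].isna()
    if missing.any():
        skipped = sorted(merged.loc[missing, "subject_id"].unique())
        warnings.warn(f"no mature-phase visits; skipping subjects {skipped}",
                      stacklevel=2)
        merged = merged[~missing]
    merged = merged.copy()
    merged["multiplier"] = merged["adult_t1s1"] / merged["t1s1"]
    return merged.drop(columns="adult_t1s1")


def build_multiplier_table(observations: pd.DataFrame,
                           grid: np.ndarray = DEFAULT_GRID) -> pd.DataFrame:
    """Bin multiplier observations onto the timing grid.

    Per grid point t and method, the mean/sd/n of observations with timing in
    [t - 0.25, t + 0.25).  Means are clamped to >= 1.000 (a mature spine
    cannot shrink in this framework).  Empty bins stay NaN -- they are never
    silently interpolated.

    Returns a DataFrame indexed by timing with a (method, stat) column
    MultiIndex, stats ``mean``, ``sd``, ``n``.
    """
    methods = sorted(observations["method"].unique())
    cols = pd.MultiIndex.from_product([methods, ("mean", "sd", "n")])
    table = pd.DataFrame(index=pd.Index(grid, name="timing"), columns=cols,
                         dtype=float)
    for t in grid:
        in_bin = observations[
            (observations["timing"] >= t - BIN_HALFWIDTH)
            & (observations["timing"] < t + BIN_HALFWIDTH)
        ]
        for method, grp in in_bin.groupby("method"):
            vals = grp["multiplier"].to_numpy()
            table.loc[t, (method, "mean")] = max(1.0, float(vals.mean()))
            table.loc[t, (method, "sd")] = (float(vals.std(ddof=1))
                                            if len(vals) > 1 else 0.0)
            table.loc[t, (method, "n")] = float(len(vals))
    return table


def interpolate_multiplier(column: pd.Series, timing: float) -> float:
    """Linear interpolation of a multiplier column; exact at grid points.

    ``column`` is indexed by timing (as in the reference table).  Timings
    past the end of the grid return 1.0 (the spine is mature); timings before
    the grid are refused rather than extrapolated.
    """
    timings = np.asarray(column.index, dtype=float)
    values = np.asarray(column, dtype=float)
    if timing > timings[-1]:
        return 1.0
    if timing < timings[0]:
        raise AnalysisError(
            f"timing {timing} before the start of the multiplier grid "
            f"({timings[0]})", code="OUT_OF_RANGE",
        )
    if np.isnan(values).any():
        raise AnalysisError("multiplier column has empty cells; refusing to "
                            "interpolate across them", code="MISSING_CELL")
    return float(np.interp(timing, timings, values))


@dataclass(frozen=True)
class SpinePrediction:
    point: float
    lower: float
    upper: float
    lower_method: str
    upper_method: str


def predict_adult_spine(current_t1s1: float, timing: float,
                        table: pd.DataFrame) -> SpinePrediction:
    """Predict adult T1-S1 with a (lower, upper) bracket.

    The percent-C1-S1 and body-height multiplier columns of ``table`` give
    two predictions; the bracket is ordered by value (the columns cross near
    timing -0.5, so neither is uniformly the lower one) and the point
    estimate is their midpoint.
    """
    if current_t1s1 <= 0:
        raise AnalysisError("current T1-S1 must be positive", code="OUT_OF_RANGE")
    preds = {
        name: current_t1s1 * interpolate_multiplier(table[name], timing)
        for name in ("percent_c1s1", "body_height")
    }
    lower_method = min(preds, key=preds.get)
    upper_method = max(preds, key=preds.get)
    lower, upper = preds[lower_method], preds[upper_method]
    return SpinePrediction(point=0.5 * (lower + upper), lower=lower,
                           upper=upper, lower_method=lower_method,
                           upper_method=upper_method)


# -- spline fits and the timing-vs-age comparison --------------------------

@dataclass
class SplineFit:
    """A cubic smoothing-spline fit of multiplier against one predictor."""

    predictor: str
    spline: object
    fitted: np.ndarray
    residuals: np.ndarray
    index: pd.Index
    monotone_decreasing: bool


def fit_multiplier_spline(observations: pd.DataFrame, predictor: str = "timing",
                          sex: str | None = None,
                          lam: float | None = None) -> SplineFit:
    """Cubic smoothing spline of multiplier vs timing or age.

    Smoothing is selected by generalized cross-validation (``lam=None``).
    Observations sharing a predictor value are merged into one weighted point
    before fitting (the spline basis needs strictly increasing abscissae);
    residuals are still reported per original observation.  Whether the fitted
    curve is monotone decreasing is reported as a diagnostic, not enforced.
    """
    if sex is not None:
        observations = observations[observations["sex"] == sex]
    if len(observations) < 20:
        raise AnalysisError(
            f"need >= 20 observations for a spline fit, got {len(observations)}",
            code="TOO_FEW_POINTS",
        )
    x = observations[predictor].to_numpy(dtype=float)
    y = observations["multiplier"].to_numpy(dtype=float)
    grouped = pd.DataFrame({"x": x, "y": y}).groupby("x")["y"].agg(["mean", "count"])
    xu = grouped.index.to_numpy(dtype=float)
    spl = make_smoothing_spline(xu, grouped["mean"].to_numpy(),
                                w=grouped["count"].to_numpy(dtype=float),
                                lam=lam)
    fitted = spl(x)
    fine = np.linspace(xu[0], xu[-1], 200)
    monotone = bool(np.all(np.diff(spl(fine)) <= 1e-9))
    return SplineFit(predictor=predictor, spline=spl, fitted=fitted,
                     residuals=y - fitted, index=observations.index,
                     monotone_decreasing=monotone)


@dataclass(frozen=True)
class AvrComparison:
    median_avr_timing: float
    pooled_median_avr_age: float
    p_value: float
    n: int
    caveat: str = ("the two models use different predictors; this residual "
                   "comparison is exploratory rather than a formal model "
                   "comparison")


def avr_compare(residuals_timing: pd.Series,
                residuals_age: pd.Series) -> AvrComparison:
    """Paired Wilcoxon signed-rank test on absolute residuals (AVRs).

    ``residuals_timing`` come from the pooled-sex fit against spurt timing;
    ``residuals_age`` from the per-sex fits against chronological age, pooled.
    Both series must be indexed by the same observations (one AVR pair per
    visit).
    """
    if len(residuals_timing) != len(residuals_age) or not (
        residuals_timing.index.sort_values().equals(
            residuals_age.index.sort_values())
    ):
        raise AnalysisError("residual series are not paired by observation",
                            code="PAIRING")
    avr_t = residuals_timing.abs().sort_index()
    avr_a = residuals_age.abs().sort_index()
    diffs = (avr_t - avr_a).to_numpy()
    if np.allclose(diffs, 0.0):
        p = 1.0
    else:
        p = float(wilcoxon(diffs, zero_method="wilcox",
                           alternative="two-sided").pvalue)
    return AvrComparison(
        median_avr_timing=float(avr_t.median()),
        pooled_median_avr_age=float(avr_a.median()),
        p_value=p, n=len(avr_t),
    )


# -- phase velocities ------------------------------------------------------

def subject_phase_slopes(estimates: pd.DataFrame,
                         phases: dict[str, tuple[float, float]] = PHASES
                         ) -> pd.DataFrame:
    """Per-subject OLS slope of T1-S1 against timing within each phase.

    Phases are half-open [start, stop).  A subject contributes a slope for a
    phase only when it has >= 2 visits (with distinct timings) inside it.
    Returns columns subject_id, sex, phase, slope, n_visits.
    """
    rows = []
    for (subject_id, sex), grp in estimates.groupby(["subject_id", "sex"]):
        t = grp["timing"].to_numpy(dtype=float)
        y = grp["t1s1"].to_numpy(dtype=float)
        for phase, (a, b) in phases.items():
            mask = (t >= a) & (t < b)
            if mask.sum() < 2 or np.ptp(t[mask]) == 0:
                continue
            slope = float(np.polyfit(t[mask], y[mask], 1)[0])
            rows.append({"subject_id": subject_id, "sex": sex, "phase": phase,
                         "slope": slope, "n_visits": int(mask.sum())})
    return pd.DataFrame(rows, columns=["subject_id", "sex", "phase", "slope",
                                       "n_visits"])


def phase_velocity_summary(slopes: pd.DataFrame) -> pd.DataFrame:
    """Cross-subject summary of phase slopes: mean, sem, sd, n per sex/phase.

    Mirrors the layout of the published velocity table (mean with sem and sd
    in parentheses); cells with no contributing subject are absent.
    """
    out = (slopes.groupby(["sex", "phase"])["slope"]
           .agg(mean="mean", sd=lambda s: s.std(ddof=1), n="count")
           .reset_index())
    out["sd"] = out["sd"].fillna(0.0)
    out["sem"] = out["sd"] / np.sqrt(out["n"])
    order = {p: i for i, p in enumerate(PHASE_ORDER)}
    out = out.sort_values(["sex", "phase"],
                          key=lambda c: c.map(order) if c.name == "phase" else c)
    return out[["sex", "phase", "mean", "sem", "sd", "n"]].reset_index(drop=True)


# -- segmental arithmetic --------------------------------------------------

@dataclass(frozen=True)
class SegmentalRates:
    """Per-segment growth rates (mm/segment/yr) spread over the spine.

    Velocity v cm/yr splits into a thoracic share (63% over 12 segments) and
    a lumbar share (27% over 5 segments); rates are reported to 0.1 mm.
    """

    thoracic_fraction: float
    lumbar_fraction: float
    n_thoracic: int
    n_lumbar: int
    rates: pd.DataFrame  # sex, phase, velocity_cm_yr, thoracic_mm, lumbar_mm


def segmental_rates(velocities: pd.DataFrame,
                    thoracic_fraction: float = THORACIC_FRACTION,
                    lumbar_fraction: float = LUMBAR_FRACTION,
                    n_thoracic: int = N_THORACIC,
                    n_lumbar: int = N_LUMBAR) -> SegmentalRates:
    """Convert phase velocities (cm/yr) to per-segment rates (mm/segment/yr).

    ``velocities`` needs columns sex, phase, mean (cm/yr), e.g. the output of
    :func:`phase_velocity_summary`.
    """
    if thoracic_fraction + lumbar_fraction > 1.0 + 1e-12:
        raise AnalysisError("regional fractions exceed 1", code="OUT_OF_RANGE")
    rows = []
    for _, row in velocities.iterrows():
        v_mm = row["mean"] * 10.0
        rows.append({
            "sex": row["sex"], "phase": row["phase"],
            "velocity_cm_yr": row["mean"],
            "thoracic_mm_per_segment_yr": round_half_away(
                v_mm * thoracic_fraction / n_thoracic, 1),
            "lumbar_mm_per_segment_yr": round_half_away(
                v_mm * lumbar_fraction / n_lumbar, 1),
        })
    return SegmentalRates(thoracic_fraction, lumbar_fraction, n_thoracic,
                          n_lumbar, pd.DataFrame(rows))
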