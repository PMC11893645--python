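"""External-consistency check against a pelvic-width spine-length model.

Pelvic width predicts spine length well enough to serve as an independent
sanity check on reconstructed T1-S1 heights.  The published regression
coefficients belong to external work and are not embedded here: the model
must be supplied explicitly (or calibrated on data you trust, e.g. synthetic
ground truth via :func:`calibrate_pelvic_model`), and the headline statistic
is the fraction of reconstructions falling inside the model's confidence
band.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import AnalysisError


@dataclass(frozen=True)
class PelvicWidthModel:
    """Linear spine-length-from-pelvic-width model with a confidence band.

    ``ci_halfwidth`` may be a constant (cm) or a callable of pelvic width.
    """

    intercept: float
    slope: float
    ci_halfwidth: float | Callable[[float], float]

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise AnalysisError("slope must be positive", code="MODEL_REQUIRED")

    def halfwidth(self, width: float) -> float:
        if callable(self.ci_halfwidth):
            return float(self.ci_halfwidth(width))
        return float(self.ci_halfwidth)


def pelvic_predict(model: PelvicWidthModel | None,
                   pelvic_width: float) -> tuple[float, float, float]:
    """Predicted spine length and confidence band at one pelvic width."""
    if model is None:
        raise AnalysisError("a pelvic-width model must be supplied explicitly",
                            code="MODEL_REQUIRED")
    point = model.intercept + model.slope * pelvic_width
    hw = model.halfwidth(pelvic_width)
    return point, point - hw, point + hw


def calibrate_pelvic_model(pelvic_widths, spine_lengths,
                           level: float = 0.95) -> PelvicWidthModel:
    """Fit a pelvic-width model by OLS with a constant pointwise band.

    The band half-width is z * residual sd at the requested coverage level.
    Intended for tests and synthetic studies where a trusted reference model
    is unavailable.
    """
    x = np.asarray(pelvic_widths, dtype=float)
    y = np.asarray(spine_lengths, dtype=float)
    if len(x) < 3:
        raise AnalysisError("need >= 3 points to calibrate", code="NO_PAIRS")
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (intercept + slope * x)
    z = float(norm.ppf(0.5 + level / 2))
    hw = z * float(np.std(resid, ddof=2))
    return PelvicWidthModel(intercept=float(intercept), slope=float(slope),
                            ci_halfwidth=hw)


def agreement_rate(estimates: pd.DataFrame, widths: pd.DataFrame,
                   model: PelvicWidthModel | None) -> pd.DataFrame:
    """Fraction of spine estimates inside the pelvic-width band, per method.

    ``estimates`` needs columns subject_id, age, method, t1s1; ``widths``
    needs subject_id, age, pelvic_width.  Visits without a pelvic width are
    skipped (radiographs were not always measurable), and the number of
    usable pairs is reported alongside each rate.
    """
    if model is None:
        raise AnalysisError("a pelvic-width model must be supplied explicitly",
                            code="MODEL_REQUIRED")
    widths = widths.dropna(subset=["pelvic_width"])
    # pair on age rounded to 0.001 yr so values that crossed a CSV round-trip
    # still match their visit
    est = estimates.assign(_age_key=estimates["age"].round(3))
    wid = widths.assign(_age_key=widths["age"].round(3))
    paired = est.merge(wid[["subject_id", "_age_key", "pelvic_width"]],
                       on=["subject_id", "_age_key"], how="inner")
    if paired.empty:
        raise AnalysisError("no visits with both a spine estimate and a "
                            "pelvic width", code="NO_PAIRS")
    point = model.intercept + model.slope * paired["pelvic_width"]
    hw = paired["pelvic_width"].map(model.halfwidth)
    inside = (paired["t1s1"] >= point - hw) & (paired["t1s1"] <= point + hw)
    out = (pd.DataFrame({"method": paired["method"], "inside": inside})
           .groupby("method")["inside"].agg(rate="mean", n_pairs="count")
           .reset_index())
    out["n_pairs"] = out["n_pairs"].astype(int)
    return out
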