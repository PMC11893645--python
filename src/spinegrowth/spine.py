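"""Per-visit T1-S1 (and C1-S1) spine-height reconstruction.

Three reconstruction methods, all anchored on a common S1 height (a pelvic
landmark height plus its radiographic offset to the top of S1):

``direct``
    T1 height (sternal notch + radiographic notch-to-T1 offset) minus S1
    height.  Uses only that visit's measurements.
``c1s1_fraction``
    C1 height approximated as stature minus head height (optionally refined
    by the EAM-to-C1 offset); T1-S1 taken as a fixed fraction of the C1-S1
    span (cohort median ~76.2%).
``body_regression``
    Spine measure recovered from standing height through a proportionality
    constant fitted by regression through the origin
    (body = beta * spine + error).  The fit and the inversion must share a
    units convention, which travels inside :class:`BetaFit`.
"""

from __future__ import annotations

import statistics
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .cohort import PelvicLandmark, SubjectSeries, VisitRecord
from .errors import AnalysisError
from .reference import C1S1_RATIO, EAM_C1_OFFSET_CM

#: Landmark preference when the visit does not name one: most reliable first.
LANDMARK_PRIORITY = (PelvicLandmark.SYMPHYSIS, PelvicLandmark.CREST,
                     PelvicLandmark.ASIS)

_LANDMARK_FIELD = {
    PelvicLandmark.SYMPHYSIS: "h_symphysis",
    PelvicLandmark.CREST: "h_iliac_crest",
    PelvicLandmark.ASIS: "h_asis",
}


@dataclass(frozen=True)
class SpineEstimate:
    subject_id: str
    age: float
    method: str
    t1s1: float
    s1_height: float
    c1s1: float | None = None
    provenance: str | None = None


@dataclass(frozen=True)
class BetaFit:
    """Regression-through-origin fit of body height on spine height."""

    beta_hat: float
    n_points: int
    residual_sd: float
    convention: str = "raw_cm"


def s1_height(visit: VisitRecord) -> tuple[float, PelvicLandmark]:
    """S1 height = pelvic landmark height + signed radiographic offset.

    Uses the landmark the visit records; if none is recorded, falls back to
    the fixed priority symphysis > crest > ASIS so runs are reproducible.
    Returns the height and the landmark actually used.
    """
    if visit.off_pelvis_S1 is None:
        raise AnalysisError("off_pelvis_S1 missing", code="S1_UNAVAILABLE")
    candidates = ((visit.pelvic_landmark,) if visit.pelvic_landmark is not None
                  else LANDMARK_PRIORITY)
    for lm in candidates:
        h = getattr(visit, _LANDMARK_FIELD[lm])
        if h is not None:
            return h + visit.off_pelvis_S1, lm
    raise AnalysisError(
        f"no pelvic landmark height available (looked for "
        f"{[lm.value for lm in candidates]})", code="S1_UNAVAILABLE",
    )


def method1_t1s1(visit: VisitRecord) -> SpineEstimate:
    """Direct reconstruction: T1 height minus S1 height."""
    if visit.h_sternal_notch is None or visit.off_notch_T1 is None:
        raise AnalysisError("sternal notch height or notch-to-T1 offset missing",
                            code="MISSING_MEASUREMENT")
    s1, landmark = s1_height(visit)
    t1 = visit.h_sternal_notch + visit.off_notch_T1
    span = t1 - s1
    if span <= 0:
        raise AnalysisError(
            f"non-positive T1-S1 span ({span:.2f} cm): inconsistent offsets",
            code="NEGATIVE_SPAN",
        )
    return SpineEstimate(visit.subject_id, visit.age, "direct", span, s1,
                         provenance=landmark.value)


def method2_t1s1(visit: VisitRecord, ratio: float = C1S1_RATIO,
                 apply_eam_offset: bool = False) -> SpineEstimate:
    """Fixed-fraction reconstruction from the approximate C1-S1 span.

    C1 is approximated as stature minus head height.  With
    ``apply_eam_offset`` the C1 estimate is raised by the visit's measured
    EAM-to-C1 offset (default 1.7 cm when unmeasured); off by default because
    the operative definition of the approximate C1 is simply vertex minus
    head height.
    """
    if visit.head_height is None:
        raise AnalysisError("head height missing", code="MISSING_MEASUREMENT")
    s1, landmark = s1_height(visit)
    c1 = visit.standing_height - visit.head_height
    if apply_eam_offset:
        c1 += visit.off_eam_C1 if visit.off_eam_C1 is not None else EAM_C1_OFFSET_CM
    c1s1 = c1 - s1
    if c1s1 <= 0:
        raise AnalysisError(f"non-positive C1-S1 span ({c1s1:.2f} cm)",
                            code="NEGATIVE_SPAN")
    return SpineEstimate(visit.subject_id, visit.age, "c1s1_fraction",
                         ratio * c1s1, s1, c1s1=c1s1, provenance=landmark.value)


def reconstructed_c1s1(visit: VisitRecord) -> float:
    """Approximate C1-S1 span: (stature - head height) - S1 height."""
    if visit.head_height is None:
        raise AnalysisError("head height missing", code="MISSING_MEASUREMENT")
    s1, _ = s1_height(visit)
    return (visit.standing_height - visit.head_height) - s1


@dataclass(frozen=True)
class RatioEstimate:
    median: float
    sd: float
    n: int


def summarize_ratios(ratios: Sequence[float]) -> RatioEstimate:
    """Median and sd of pooled per-visit T1-S1/C1-S1 ratios."""
    ratios = list(ratios)
    if len(ratios) < 10:
        warnings.warn(f"only {len(ratios)} ratio observations (LOW_N)",
                      stacklevel=2)
    sd = float(np.std(ratios, ddof=1)) if len(ratios) > 1 else 0.0
    return RatioEstimate(median=float(statistics.median(ratios)), sd=sd,
                         n=len(ratios))


def estimate_c1s1_ratio(cohort: Iterable[SubjectSeries]) -> RatioEstimate:
    """Pooled per-visit ratio of direct T1-S1 to reconstructed C1-S1.

    Every visit (across all subjects) with both a direct reconstruction and
    an approximate C1-S1 span contributes one ratio; visits lacking the
    required measurements are skipped.
    """
    ratios: list[float] = []
    for series in cohort:
        for visit in series.visits:
            try:
                t1s1 = method1_t1s1(visit).t1s1
                c1s1 = reconstructed_c1s1(visit)
            except AnalysisError:
                continue
            if c1s1 > 0:
                ratios.append(t1s1 / c1s1)
    return summarize_ratios(ratios)


def fit_beta(pairs: Iterable[tuple[float, float]],
             convention: str = "raw_cm") -> BetaFit:
    """Regression through the origin of body height on spine height.

    Closed form ``beta = sum(x*y) / sum(x^2)``; residual sd uses an n-1
    denominator.
    """
    arr = np.asarray(list(pairs), dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise AnalysisError("need >= 2 (spine, body) pairs", code="DEGENERATE")
    x, y = arr[:, 0], arr[:, 1]
    sxx = float(np.sum(x * x))
    if sxx == 0:
        raise AnalysisError("all spine heights zero", code="DEGENERATE")
    beta = float(np.sum(x * y) / sxx)
    resid = y - beta * x
    residual_sd = float(np.sqrt(np.sum(resid ** 2) / (len(x) - 1)))
    return BetaFit(beta_hat=beta, n_points=len(x), residual_sd=residual_sd,
                   convention=convention)


def method3_t1s1(visit: VisitRecord, beta_fit: BetaFit,
                 convention: str = "raw_cm") -> SpineEstimate:
    """Regression reconstruction: spine measure = standing height / beta.

    The returned value is on whatever scale beta was fitted with; callers
    must request the convention they expect, and a mismatch raises rather
    than silently mixing scales.
    """
    if beta_fit.convention != convention:
        raise AnalysisError(
            f"beta fitted under {beta_fit.convention!r}, inversion requested "
            f"under {convention!r}", code="CONVENTION",
        )
    return SpineEstimate(visit.subject_id, visit.age, "body_regression",
                         visit.standing_height / beta_fit.beta_hat,
                         s1_height=float("nan"))
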