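"""Growth completion, adult height, and growth-spurt alignment.

A child is considered to have completed growth when standing height increased
by less than 1 cm/yr between the last two visits; adult height is then the
final-visit height.  Each subject's spurt timing is summarised by the PGA90%
age -- the age at which interpolated standing height first reaches 90% of
adult height, a robust surrogate for the timing of peak height velocity.
Aligning visits on (age - PGA90% age) puts all children on a common maturity
axis regardless of when their spurt happened.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import PchipInterpolator
from sklearn.isotonic import IsotonicRegression

from .cohort import SubjectSeries, VisitRecord
from .errors import AnalysisError, CohortValidationError

MATURITY_VELOCITY_CM_PER_YR = 1.0
PGA_HEIGHT_FRACTION = 0.90


@dataclass
class MaturityAssessment:
    subject_id: str
    is_mature: bool
    adult_height: float
    final_velocity: float
    pga90_age: float | None = None
    qc_notes: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class AlignedVisit:
    """A visit stamped with its timing (yr) relative to the subject's PGA90%."""

    visit: VisitRecord
    timing: float


def assess_maturity(series: SubjectSeries) -> MaturityAssessment:
    """Apply the < 1 cm/yr final-interval criterion.

    The annualised velocity uses only the last inter-visit interval, exactly
    as the criterion reads; adult height is the final-visit standing height
    (the criterion already bounds residual growth, and taking the maximum
    instead would bias upward under measurement noise).
    """
    if len(series) < 2:
        raise CohortValidationError(
            f"subject {series.subject_id}: need >= 2 visits to assess maturity"
        )
    prev, last = series.visits[-2], series.visits[-1]
    dt = last.age - prev.age
    if dt <= 0:
        raise CohortValidationError(
            f"subject {series.subject_id}: non-positive final age interval"
        )
    velocity = (last.standing_height - prev.standing_height) / dt
    return MaturityAssessment(
        subject_id=series.subject_id,
        is_mature=velocity < MATURITY_VELOCITY_CM_PER_YR,
        adult_height=last.standing_height,
        final_velocity=velocity,
    )


def _monotone_height_interpolant(series: SubjectSeries) -> PchipInterpolator:
    """Monotone interpolant of the height series.

    Measurement noise can make raw heights locally non-monotone; an isotonic
    (pool-adjacent-violators) pre-fit restores monotonicity, after which a
    shape-preserving piecewise cubic (PCHIP) through the smoothed points is
    itself monotone, so the 90% crossing is unique.
    """
    ages = series.ages
    iso = IsotonicRegression(increasing=True)
    smoothed = iso.fit_transform(ages, series.standing_heights)
    return PchipInterpolator(ages, smoothed)


def interpolated_height(series: SubjectSeries, age: float) -> float:
    """Standing height at ``age`` under the monotone interpolant."""
    return float(_monotone_height_interpolant(series)(age))


def estimate_pga90(series: SubjectSeries, adult_height: float,
                   fraction: float = PGA_HEIGHT_FRACTION,
                   tol_yr: float = 1e-8) -> float:
    """Age at which interpolated height first reaches ``fraction`` of adult.

    The crossing is located by bisection on the monotone interpolant within
    the first bracketing visit interval, so it is a *first* crossing even
    where the fit plateaus at the target value.

    Raises
    ------
    AnalysisError
        ``FIRST_VISIT_TOO_LATE`` if the subject is already past the target at
        the first visit; ``NOT_MATURE`` if the target is never reached.
    """
    target = fraction * adult_height
    ages = series.ages
    interp = _monotone_height_interpolant(series)
    smoothed = interp(ages)
    if smoothed[0] > target:
        raise AnalysisError(
            f"subject {series.subject_id}: first visit already above "
            f"{fraction:.0%} of adult height", code="FIRST_VISIT_TOO_LATE",
        )
    if smoothed[-1] < target:
        raise AnalysisError(
            f"subject {series.subject_id}: {fraction:.0%} of adult height never "
            "reached", code="NOT_MATURE",
        )
    # first visit at or above target brackets the crossing on its left interval
    first = int(np.argmax(smoothed >= target))
    if first == 0:
        return float(ages[0])  # first visit sits exactly on the target
    lo, hi = float(ages[first - 1]), float(ages[first])
    while hi - lo > tol_yr:
        mid = 0.5 * (lo + hi)
        if interp(mid) >= target:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def assess_subject(series: SubjectSeries) -> MaturityAssessment:
    """Full assessment: maturity criterion plus PGA90% age when mature."""
    assessment = assess_maturity(series)
    if assessment.is_mature:
        try:
            assessment.pga90_age = estimate_pga90(series, assessment.adult_height)
        except AnalysisError as err:
            assessment.qc_notes.append(err.code)
    else:
        assessment.qc_notes.append("NOT_MATURE")
    return assessment


def align_visits(series: SubjectSeries,
                 assessment: MaturityAssessment) -> list[AlignedVisit]:
    """Stamp every visit with timing = age - PGA90% age."""
    if assessment.pga90_age is None:
        raise AnalysisError(
            f"subject {series.subject_id}: no PGA90% age available",
            code="NOT_MATURE",
        )
    return [AlignedVisit(v, v.age - assessment.pga90_age) for v in series.visits]
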