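"""Longitudinal cohort data model and CSV input/output.

The longitudinal unit is a :class:`SubjectSeries`: one child, one sex, and an
age-ordered list of measurement occasions (:class:`VisitRecord`).  Each visit
carries floor-referenced anthropometric landmark heights (cm) plus signed
radiograph-derived vertical offsets (cm, upward-positive), so that

    landmark height + offset = height of the bony structure above the floor.

Internally everything is centimetres.  Files may be stored in cm or mm; the
unit is declared explicitly by the caller, never auto-detected.  Missing
optional measurements are empty CSV cells and ``None`` in memory -- a zero
height is never a real measurement and is rejected by validation.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import CohortValidationError, SchemaError


class Sex(str, enum.Enum):
    FEMALE = "F"
    MALE = "M"

    @classmethod
    def parse(cls, value: "str | Sex") -> "Sex":
        if isinstance(value, Sex):
            return value
        v = str(value).strip().upper()
        if v in ("F", "FEMALE"):
            return cls.FEMALE
        if v in ("M", "MALE"):
            return cls.MALE
        raise CohortValidationError(f"unknown sex {value!r}")


class PelvicLandmark(str, enum.Enum):
    SYMPHYSIS = "symphysis"
    CREST = "crest"
    ASIS = "asis"


@dataclass(frozen=True)
class VisitRecord:
    """One measurement occasion.

    Heights are floor-referenced vertical distances in cm; ``off_*`` fields are
    signed radiographic offsets in cm, positive pointing upward (so a positive
    ``off_notch_T1`` places the top of T1 above the sternal notch).
    """

    subject_id: str
    sex: Sex
    age: float
    standing_height: float
    h_sternal_notch: float | None = None
    sitting_height: float | None = None
    h_symphysis: float | None = None
    h_iliac_crest: float | None = None
    h_asis: float | None = None
    h_trochanter: float | None = None
    head_height: float | None = None
    off_notch_T1: float | None = None
    off_pelvis_S1: float | None = None
    pelvic_landmark: PelvicLandmark | None = None
    off_eam_C1: float | None = None
    pelvic_width: float | None = None


@dataclass
class SubjectSeries:
    """All visits of one child, strictly increasing in age."""

    subject_id: str
    sex: Sex
    visits: list[VisitRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        ages = [v.age for v in self.visits]
        if any(b <= a for a, b in zip(ages, ages[1:])):
            raise CohortValidationError(
                f"subject {self.subject_id}: visit ages not strictly increasing",
                code="NONMONOTONE_AGE",
            )
        for v in self.visits:
            if v.subject_id != self.subject_id or v.sex != self.sex:
                raise CohortValidationError(
                    f"subject {self.subject_id}: visit carries mismatched identity"
                )

    @property
    def ages(self) -> np.ndarray:
        return np.array([v.age for v in self.visits])

    @property
    def standing_heights(self) -> np.ndarray:
        return np.array([v.standing_height for v in self.visits])

    def __len__(self) -> int:
        return len(self.visits)


@dataclass(frozen=True)
class Finding:
    """One machine-readable validation finding."""

    code: str
    visit_index: int | None
    message: str


# CSV schema ---------------------------------------------------------------

MANDATORY_COLUMNS = ("subject_id", "sex", "age_yr", "standing_height")
OPTIONAL_COLUMNS = (
    "sitting_height", "h_sternal_notch", "h_symphysis", "h_iliac_crest",
    "h_asis", "h_trochanter", "head_height", "off_notch_T1", "off_pelvis_S1",
    "pelvic_landmark", "off_eam_C1", "pelvic_width",
)
ALL_COLUMNS = MANDATORY_COLUMNS + OPTIONAL_COLUMNS

# columns holding lengths, converted between cm and mm
_LENGTH_COLUMNS = tuple(
    c for c in ALL_COLUMNS
    if c not in ("subject_id", "sex", "age_yr", "pelvic_landmark")
)
# strictly positive heights (offsets are signed and may legitimately be < 0)
_HEIGHT_COLUMNS = tuple(
    c for c in _LENGTH_COLUMNS if not c.startswith("off_")
)

_FIELD_BY_COLUMN = {
    "age_yr": "age",
    **{c: c for c in ALL_COLUMNS if c not in ("age_yr", "sex", "subject_id")},
}


def _check_units(units: str) -> float:
    if units == "cm":
        return 1.0
    if units == "mm":
        return 0.1
    raise SchemaError(f"units must be 'cm' or 'mm', got {units!r}")


def read_cohort_csv(path: str | Path, units: str = "cm") -> list[SubjectSeries]:
    """Read a cohort CSV into a list of :class:`SubjectSeries`.

    Parameters
    ----------
    path : str or Path
        CSV with a mandatory header; see :data:`ALL_COLUMNS` for the dialect.
    units : {"cm", "mm"}
        Unit the file's lengths are stored in.  Millimetre files are converted
        to centimetres on read.  Never inferred from the data.

    Raises
    ------
    SchemaError
        If a mandatory column is absent.
    CohortValidationError
        On duplicate (subject, age) rows, non-positive or zero heights.
    """
    scale = _check_units(units)
    df = pd.read_csv(path, dtype={"subject_id": str, "pelvic_landmark": str})
    for col in MANDATORY_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"missing mandatory column {col!r}")

    series: list[SubjectSeries] = []
    for subject_id, grp in df.groupby("subject_id", sort=True):
        grp = grp.sort_values("age_yr")
        ages = grp["age_yr"].to_numpy(dtype=float)
        if len(np.unique(ages)) != len(ages):
            raise CohortValidationError(
                f"subject {subject_id}: duplicate visit ages", code="DUPLICATE_AGE"
            )
        sexes = {Sex.parse(s) for s in grp["sex"]}
        if len(sexes) != 1:
            raise CohortValidationError(f"subject {subject_id}: inconsistent sex")
        sex = sexes.pop()
        visits = []
        for _, row in grp.iterrows():
            kwargs: dict = {"subject_id": str(subject_id), "sex": sex,
                            "age": float(row["age_yr"])}
            for col in _LENGTH_COLUMNS:
                if col not in row.index:
                    continue
                val = row[col]
                if pd.isna(val):
                    continue
                val = float(val) * scale
                if col in _HEIGHT_COLUMNS and val <= 0:
                    raise CohortValidationError(
                        f"subject {subject_id}: non-positive {col} at age "
                        f"{row['age_yr']}", code="NONPOSITIVE_HEIGHT",
                    )
                kwargs[_FIELD_BY_COLUMN[col]] = val
            lm = row.get("pelvic_landmark")
            if isinstance(lm, str) and lm.strip():
                kwargs["pelvic_landmark"] = PelvicLandmark(lm.strip())
            visits.append(VisitRecord(**kwargs))
        series.append(SubjectSeries(str(subject_id), sex, visits))
    return series


def write_cohort_csv(cohort: Sequence[SubjectSeries], path: str | Path,
                     units: str = "cm") -> None:
    """Write a cohort in the CSV dialect read by :func:`read_cohort_csv`.

    Round-trips with :func:`read_cohort_csv` to better than 0.01 cm per field.
    Missing optional values become empty cells, never zeros.
    """
    scale = 1.0 / _check_units(units)
    rows = []
    for s in cohort:
        for v in s.visits:
            row: dict = {"subject_id": s.subject_id, "sex": s.sex.value,
                         "age_yr": v.age}
            for col in _LENGTH_COLUMNS:
                val = getattr(v, _FIELD_BY_COLUMN[col])
                row[col] = "" if val is None else round(val * scale, 4)
            row["pelvic_landmark"] = (
                v.pelvic_landmark.value if v.pelvic_landmark is not None else ""
            )
            rows.append(row)
    df = pd.DataFrame(rows, columns=list(ALL_COLUMNS))
    df.to_csv(path, index=False)


def validate_series(series: SubjectSeries) -> list[Finding]:
    """Check cohort invariants; return findings instead of raising.

    Findings are deterministic and ordered by (visit index, code) so that
    repeated runs on identical input produce identical reports.
    """
    findings: list[Finding] = []
    if len(series.visits) < 2:
        findings.append(Finding("TOO_FEW_VISITS", None,
                                f"{len(series.visits)} visit(s); need >= 2"))
    ages = [v.age for v in series.visits]
    for i, (a, b) in enumerate(zip(ages, ages[1:])):
        if b <= a:
            findings.append(Finding("NONMONOTONE_AGE", i + 1,
                                    f"age {b} not after {a}"))
    for i, v in enumerate(series.visits):
        if v.age <= 0:
            findings.append(Finding("NONPOSITIVE_AGE", i, f"age {v.age}"))
        for name in ("standing_height", "sitting_height", "h_sternal_notch",
                     "h_symphysis", "h_iliac_crest", "h_asis", "h_trochanter",
                     "head_height", "pelvic_width"):
            val = getattr(v, name)
            if val is not None and val <= 0:
                findings.append(Finding("NONPOSITIVE_HEIGHT", i,
                                        f"{name} = {val}"))
        if v.head_height is not None and v.head_height >= v.standing_height:
            findings.append(Finding("HEAD_GT_STATURE", i,
                                    f"head {v.head_height} >= stature "
                                    f"{v.standing_height}"))
        for name in ("h_sternal_notch", "h_symphysis", "h_iliac_crest",
                     "h_asis", "h_trochanter"):
            val = getattr(v, name)
            if val is not None and val >= v.standing_height:
                findings.append(Finding("LANDMARK_GT_STATURE", i,
                                        f"{name} = {val} >= stature"))
        if v.off_pelvis_S1 is not None and all(
            getattr(v, n) is None
            for n in ("h_symphysis", "h_iliac_crest", "h_asis")
        ):
            findings.append(Finding("PELVIC_OFFSET_NO_LANDMARK", i,
                                    "off_pelvis_S1 without any pelvic landmark"))
    findings.sort(key=lambda f: (math.inf if f.visit_index is None
                                 else f.visit_index, f.code))
    return findings
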