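"""Exception hierarchy.

Every error raised by this package carries a short machine-readable ``code``
so pipeline drivers can report failures without string-matching messages.
"""

from __future__ import annotations


class SpineGrowthError(Exception):
    """Base class for all package errors."""

    def __init__(self, message: str, code: str = "GENERIC"):
        super().__init__(message)
        self.code = code


class SchemaError(SpineGrowthError):
    """A CSV file does not match the documented cohort schema."""

    def __init__(self, message: str):
        super().__init__(message, code="SCHEMA")


class CohortValidationError(SpineGrowthError):
    """Input data violates a cohort invariant (named in the message)."""

    def __init__(self, message: str, code: str = "VALIDATION"):
        super().__init__(message, code=code)


class ConfigError(SpineGrowthError):
    """A generator or pipeline configuration is internally inconsistent."""

    def __init__(self, message: str):
        super().__init__(message, code="CONFIG")


class AnalysisError(SpineGrowthError):
    """A computation cannot proceed on the given inputs.

    Codes in use: ``S1_UNAVAILABLE``, ``NEGATIVE_SPAN``, ``DEGENERATE``,
    ``CONVENTION``, ``OUT_OF_RANGE``, ``MISSING_CELL``, ``PAIRING``,
    ``MODEL_REQUIRED``, ``NO_PAIRS``, ``FIRST_VISIT_TOO_LATE``, ``NOT_MATURE``,
    ``TOO_FEW_POINTS``.
    """
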