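"""Published reference constants for periadolescent spinal growth.

These are the headline results of the Bolton-Brush longitudinal spinal growth
analysis, embedded so that predictions can be made without re-deriving them
from data:

* the growth-remaining multiplier table on the timing grid -4.0 .. +4.5 years
  relative to PGA90% (the age at which a child reaches 90% of adult standing
  height), with one column per reconstruction convention -- T1-S1 as a fixed
  percentage of C1-S1 ("percent C1-S1") and T1-S1 from its statistical
  relationship to standing height ("relative to body height");
* T1-S1 growth velocities (cm/yr) per sex for the four growth phases defined
  by fixed knots at -2, +2 and +4 years from PGA90%;
* the thoracic/lumbar shares of T1-S1 height used for segmental arithmetic.

A multiplier is adult length divided by current length; its reciprocal is the
fraction of mature size already attained.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

#: Timing grid (years relative to PGA90%) of the reference multiplier table.
TABLE_TIMINGS = np.arange(-4.0, 4.51, 0.5)

#: Multipliers with T1-S1 taken as the cohort-median percentage of C1-S1.
PERCENT_C1S1_MULTIPLIERS = np.array(
    [1.336, 1.314, 1.292, 1.270, 1.248, 1.226, 1.204, 1.182, 1.160,
     1.138, 1.116, 1.094, 1.072, 1.050, 1.028, 1.006, 1.000, 1.000]
)

#: Multipliers with T1-S1 reconstructed from its regression on standing height.
BODY_HEIGHT_MULTIPLIERS = np.array(
    [1.397, 1.366, 1.336, 1.305, 1.274, 1.243, 1.211, 1.179, 1.148,
     1.117, 1.089, 1.063, 1.042, 1.026, 1.015, 1.007, 1.002, 1.000]
)


def reference_multiplier_table() -> pd.DataFrame:
    """Return the published multiplier table as a DataFrame.

    Indexed by timing (years from PGA90%), columns ``percent_c1s1`` and
    ``body_height``.
    """
    return pd.DataFrame(
        {
            "percent_c1s1": PERCENT_C1S1_MULTIPLIERS,
            "body_height": BODY_HEIGHT_MULTIPLIERS,
        },
        index=pd.Index(TABLE_TIMINGS, name="timing"),
    )


#: Growth phases relative to PGA90%, half-open intervals [start, stop).
PHASES: dict[str, tuple[float, float]] = {
    "childhood": (-math.inf, -2.0),
    "spurt": (-2.0, 2.0),
    "terminal": (2.0, 4.0),
    "mature": (4.0, math.inf),
}

PHASE_ORDER = ("childhood", "spurt", "terminal", "mature")

#: Published T1-S1 growth velocities, cm/yr, per sex and phase.
#: The mature-phase male value is a small negative slope and is reported
#: as published; it reflects estimation noise, not actual shrinkage.
PHASE_VELOCITIES: dict[str, dict[str, float]] = {
    "F": {"childhood": 1.55, "spurt": 1.75, "terminal": 0.9, "mature": 0.0474},
    "M": {"childhood": 1.14, "spurt": 2.0, "terminal": 0.881, "mature": -0.12},
}

#: Shares of T1-S1 height contributed by the thoracic and lumbar spine
#: during adolescence, and the segment counts they are spread over.
THORACIC_FRACTION = 0.63
LUMBAR_FRACTION = 0.27
N_THORACIC = 12
N_LUMBAR = 5

#: Median T1-S1 / C1-S1 ratio (and its spread) across all visits.
C1S1_RATIO = 0.762
C1S1_RATIO_SD = 0.0176

#: Vertical offset from the external auditory meatus up to the top of C1.
EAM_C1_OFFSET_CM = 1.7
EAM_C1_OFFSET_SD_CM = 0.3
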