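"""Phase-wise T1-S1 growth velocities and per-segment rates.

Reads results/spine_estimates.csv, fits per-subject OLS slopes within the
four growth phases (childhood < -2 yr, spurt -2..2, terminal 2..4, mature
>= 4 yr from PGA90%), and writes results/phase_velocities.csv plus the
segmental arithmetic (63% thoracic over 12 segments, 27% lumbar over 5) in
results/segmental_rates.csv.
"""

from pathlib import Path

import pandas as pd

from spinegrowth.analysis import (phase_velocity_summary, segmental_rates,
                                  subject_phase_slopes)

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    estimates = pd.read_csv(RESULTS / "spine_estimates.csv")
    direct = estimates[estimates["method"] == "direct"]
    summary = phase_velocity_summary(subject_phase_slopes(direct))
    summary.to_csv(RESULTS / "phase_velocities.csv", index=False,
                   float_format="%.6g")

    for _, row in summary.iterrows():
        print(f"{row['sex']} {row['phase']:>9}: "
              f"{row['mean']:.2f} cm/yr (sem {row['sem']:.2f}, "
              f"sd {row['sd']:.2f}, n={int(row['n'])})")

    seg = segmental_rates(summary)
    seg.rates.to_csv(RESULTS / "segmental_rates.csv", index=False,
                     float_format="%.6g")
    child = seg.rates[seg.rates["phase"] == "childhood"].set_index("sex")
    print(f"childhood per-segment rates: girls "
          f"{child.loc['F', 'thoracic_mm_per_segment_yr']} mm/yr, boys "
          f"{child.loc['M', 'thoracic_mm_per_segment_yr']} mm/yr")
    print(f"wrote {RESULTS / 'phase_velocities.csv'} and segmental_rates.csv")


if __name__ == "__main__":
    main()
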