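"""Apply the growth-completion criterion and locate each child's PGA90%.

Reads results/cohort.csv, writes results/maturity.csv with one row per
subject: maturity flag, adult height, final-interval velocity, PGA90% age.
"""

from pathlib import Path

import pandas as pd

from spinegrowth.cohort import read_cohort_csv
from spinegrowth.pipeline import assess_cohort

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    cohort = read_cohort_csv(RESULTS / "cohort.csv", units="cm")
    assessments = assess_cohort(cohort)
    df = pd.DataFrame([
        {"subject_id": a.subject_id, "is_mature": a.is_mature,
         "adult_height": a.adult_height, "final_velocity": a.final_velocity,
         "pga90_age": a.pga90_age, "qc_notes": ";".join(a.qc_notes)}
        for a in assessments.values()
    ])
    df.to_csv(RESULTS / "maturity.csv", index=False, float_format="%.6g")

    mature = df[df["is_mature"]]
    print(f"{len(mature)}/{len(df)} subjects meet the < 1 cm/yr criterion")
    print(f"PGA90% age: median {mature['pga90_age'].median():.2f} yr, "
          f"range {mature['pga90_age'].min():.2f}-{mature['pga90_age'].max():.2f}")
    print(f"wrote {RESULTS / 'maturity.csv'}")


if __name__ == "__main__":
    main()
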