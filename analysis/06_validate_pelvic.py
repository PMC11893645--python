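"""External-consistency check of the reconstructions against pelvic width.

Calibrates a pelvic-width spine-length model on the generator's ground
truth (results/truth.csv), then reports the fraction of per-visit T1-S1
estimates falling inside the model's 95% band, per method.  Writes
results/agreement_report.json.
"""

from pathlib import Path

import pandas as pd

from spinegrowth.cohort import Sex, read_cohort_csv
from spinegrowth.simulate import GeneratorConfig, SubjectTruth, spine_trajectory
from spinegrowth.validation import agreement_rate, calibrate_pelvic_model

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    cohort = read_cohort_csv(RESULTS / "cohort.csv", units="cm")
    truth_df = pd.read_csv(RESULTS / "truth.csv")
    truths = {
        row["subject_id"]: SubjectTruth(**{
            **{k: row[k] for k in truth_df.columns if k != "sex"},
            "sex": Sex.parse(row["sex"]),
        })
        for _, row in truth_df.iterrows()
    }
    cfg = GeneratorConfig()

    widths, spines = [], []
    for s in cohort:
        t = truths[s.subject_id]
        for v in s.visits:
            widths.append(v.pelvic_width)
            spines.append(spine_trajectory(t, cfg, v.age - t.true_pga_age))
    model = calibrate_pelvic_model(widths, spines)
    print(f"truth-calibrated model: T1-S1 = {model.intercept:.2f} + "
          f"{model.slope:.3f} x width, band +/- {model.halfwidth(0):.2f} cm")

    estimates = pd.read_csv(RESULTS / "spine_estimates.csv")
    width_table = pd.DataFrame([
        {"subject_id": s.subject_id, "age": v.age,
         "pelvic_width": v.pelvic_width}
        for s in cohort for v in s.visits
    ])
    report = agreement_rate(estimates, width_table, model)
    report.to_json(RESULTS / "agreement_report.json", orient="records",
                   indent=2)
    for _, row in report.iterrows():
        print(f"{row['method']:>15}: {100 * row['rate']:.0f}% of "
              f"{int(row['n_pairs'])} visits inside the band")
    print(f"wrote {RESULTS / 'agreement_report.json'}")


if __name__ == "__main__":
    main()
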