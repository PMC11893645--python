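"""End-to-end pipeline: simulate/load -> assess -> reconstruct -> analyze.

One :func:`run_pipeline` call executes the whole analysis and writes its
tables (CSV) and reports (JSON) plus a manifest under an output directory.
Identical configuration and seed produce byte-identical tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .analysis import (avr_compare, build_multiplier_table, compute_multipliers,
                       fit_multiplier_spline, phase_velocity_summary,
                       segmental_rates, subject_phase_slopes)
from .cohort import SubjectSeries, read_cohort_csv, write_cohort_csv
from .errors import AnalysisError, ConfigError
from .maturity import MaturityAssessment, align_visits, assess_subject
from .simulate import GeneratorConfig, generate_cohort
from .spine import (BetaFit, estimate_c1s1_ratio, fit_beta, method1_t1s1,
                    method2_t1s1, method3_t1s1)
from .validation import PelvicWidthModel, agreement_rate

log = logging.getLogger("spinegrowth")

ALL_METHODS = ("direct", "c1s1_fraction", "body_regression")


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one data source: either a generator config (synthetic cohort) or
    an input CSV path.
    """

    out_dir: str | Path
    generator: GeneratorConfig | None = None
    input_path: str | Path | None = None
    units: str = "cm"
    methods: Sequence[str] = ALL_METHODS
    seed: int = 0
    pelvic_model: PelvicWidthModel | None = None
    ratio_source: str = "cohort"  # "cohort" (estimated median) or "fixed"

    def validate(self) -> None:
        if (self.generator is None) == (self.input_path is None):
            raise ConfigError("exactly one of generator/input_path must be set")
        unknown = set(self.methods) - set(ALL_METHODS)
        if unknown:
            raise ConfigError(f"unknown methods {sorted(unknown)}")


def assess_cohort(cohort: Sequence[SubjectSeries]
                  ) -> dict[str, MaturityAssessment]:
    """Assess every subject; immature subjects keep a note, not a PGA age."""
    return {s.subject_id: assess_subject(s) for s in cohort}


def build_estimate_table(cohort: Sequence[SubjectSeries],
                         assessments: dict[str, MaturityAssessment],
                         methods: Sequence[str] = ALL_METHODS,
                         ratio: float | None = None,
                         beta_fit: BetaFit | None = None,
                         ) -> tuple[pd.DataFrame, BetaFit | None, float | None]:
    """Tidy per-visit spine estimates for all mature, aligned subjects.

    Subjects failing the maturity criterion (or lacking a PGA90% age) are
    excluded -- multipliers and velocities are only defined against a known
    adult state.  When ``ratio``/``beta_fit`` are not given they are derived
    from the cohort itself: the pooled median T1-S1/C1-S1 ratio, and a
    regression through the origin of standing height on the direct T1-S1
    reconstruction (convention ``raw_cm``).
    """
    mature = [s for s in cohort
              if assessments[s.subject_id].is_mature
              and assessments[s.subject_id].pga90_age is not None]

    if "c1s1_fraction" in methods and ratio is None:
        ratio = estimate_c1s1_ratio(mature).median
    if "body_regression" in methods and beta_fit is None:
        pairs = []
        for s in mature:
            for v in s.visits:
                try:
                    pairs.append((method1_t1s1(v).t1s1, v.standing_height))
                except AnalysisError:
                    continue
        beta_fit = fit_beta(pairs, convention="raw_cm")

    rows = []
    for s in mature:
        for av in align_visits(s, assessments[s.subject_id]):
            v = av.visit
            for method in methods:
                try:
                    if method == "direct":
                        est = method1_t1s1(v)
                    elif method == "c1s1_fraction":
                        est = method2_t1s1(v, ratio=ratio)
                    else:
                        est = method3_t1s1(v, beta_fit, convention="raw_cm")
                except AnalysisError as err:
                    log.debug("skip %s age %.2f method %s: %s",
                              s.subject_id, v.age, method, err)
                    continue
                rows.append({"subject_id": s.subject_id, "sex": s.sex.value,
                             "age": v.age, "timing": av.timing,
                             "method": method, "t1s1": est.t1s1})
    df = pd.DataFrame(rows, columns=["subject_id", "sex", "age", "timing",
                                     "method", "t1s1"])
    return df, beta_fit, ratio


def avr_report(observations: pd.DataFrame,
               method: str = "body_regression") -> dict:
    """Timing-vs-age residual comparison on one method's multipliers.

    The timing model pools sexes (timing alignment removes the sex
    difference); the age models are fitted per sex and their residuals
    pooled, mirroring how the comparison is defined.
    """
    obs = observations[observations["method"] == method]
    fit_t = fit_multiplier_spline(obs, predictor="timing")
    res_t = pd.Series(fit_t.residuals, index=fit_t.index)
    res_a_parts = []
    for sex in sorted(obs["sex"].unique()):
        fit_a = fit_multiplier_spline(obs, predictor="age", sex=sex)
        res_a_parts.append(pd.Series(fit_a.residuals, index=fit_a.index))
    res_a = pd.concat(res_a_parts)
    cmp = avr_compare(res_t, res_a)
    return {"method": method,
            "median_avr_timing": cmp.median_avr_timing,
            "pooled_median_avr_age": cmp.pooled_median_avr_age,
            "p_value": cmp.p_value, "n": cmp.n, "caveat": cmp.caveat}


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages and write tables, reports and a manifest.

    Returns the manifest (also written as ``manifest.json``).
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "version": __version__, "stages": {}}

    stage = "acquire"
    try:
        if config.generator is not None:
            gen = dataclasses.replace(config.generator, seed=config.seed)
            cohort, truths = generate_cohort(gen)
            write_cohort_csv(cohort, out / "cohort.csv", units="cm")
            truth_df = pd.DataFrame([dataclasses.asdict(t) for t in truths])
            truth_df["sex"] = [t.sex.value for t in truths]
            truth_df.to_csv(out / "truth.csv", index=False)
            manifest["source"] = {"kind": "synthetic",
                                  "config": _jsonable(dataclasses.asdict(gen))}
        else:
            cohort = read_cohort_csv(config.input_path, units=config.units)
            digest = hashlib.sha256(
                Path(config.input_path).read_bytes()).hexdigest()
            manifest["source"] = {"kind": "file",
                                  "path": str(config.input_path),
                                  "sha256": digest}
        manifest["stages"][stage] = {"n_subjects": len(cohort)}

        stage = "maturity"
        assessments = assess_cohort(cohort)
        maturity_df = pd.DataFrame(
            [{"subject_id": a.subject_id, "is_mature": a.is_mature,
              "adult_height": a.adult_height,
              "final_velocity": a.final_velocity, "pga90_age": a.pga90_age,
              "qc_notes": ";".join(a.qc_notes)}
             for a in assessments.values()])
        maturity_df.to_csv(out / "maturity.csv", index=False,
                           float_format="%.6g")
        n_mature = int(maturity_df["is_mature"].sum())
        manifest["stages"][stage] = {"n_mature": n_mature,
                                     "n_excluded": len(cohort) - n_mature}

        stage = "reconstruct"
        estimates, beta_fit, ratio = build_estimate_table(
            cohort, assessments, methods=config.methods)
        estimates.to_csv(out / "spine_estimates.csv", index=False,
                         float_format="%.6g")
        manifest["stages"][stage] = {
            "n_estimates": len(estimates),
            "beta_hat": None if beta_fit is None else beta_fit.beta_hat,
            "c1s1_ratio": ratio,
        }

        stage = "multipliers"
        observations = compute_multipliers(estimates)
        table = build_multiplier_table(observations)
        flat = table.copy()
        flat.columns = [f"{m}_{s}" for m, s in flat.columns]
        flat.to_csv(out / "multiplier_table.csv", float_format="%.6g")
        manifest["stages"][stage] = {"n_observations": len(observations),
                                     "n_grid_rows": len(table)}

        stage = "avr"
        report = avr_report(observations)
        (out / "avr_report.json").write_text(json.dumps(report, indent=2))
        manifest["stages"][stage] = {"p_value": report["p_value"]}

        stage = "velocities"
        slopes = subject_phase_slopes(
            estimates[estimates["method"] == "direct"]
            if "direct" in config.methods else estimates)
        velocities = phase_velocity_summary(slopes)
        velocities.to_csv(out / "phase_velocities.csv", index=False,
                          float_format="%.6g")
        seg = segmental_rates(velocities)
        seg.rates.to_csv(out / "segmental_rates.csv", index=False,
                         float_format="%.6g")
        manifest["stages"][stage] = {"n_slopes": len(slopes)}

        if config.pelvic_model is not None:
            stage = "validation"
            widths = pd.DataFrame(
                [{"subject_id": s.subject_id, "age": v.age,
                  "pelvic_width": v.pelvic_width}
                 for s in cohort for v in s.visits])
            agreement = agreement_rate(estimates, widths, config.pelvic_model)
            agreement.to_json(out / "agreement_report.json", orient="records",
                              indent=2)
            manifest["stages"][stage] = {
                "rates": agreement.set_index("method")["rate"].to_dict()}
    except Exception as err:
        raise AnalysisError(f"stage {stage!r} failed: {err}",
                            code="STAGE_FAILED") from err

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def configure_logging(level: str = "INFO") -> None:
    """Structured-ish stderr logging; stdout stays clean for predictions."""
    logging.basicConfig(stream=sys.stderr, level=getattr(logging, level),
                        format="%(levelname)s %(name)s %(message)s")
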