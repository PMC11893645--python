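"""Synthetic longitudinal cohort generator.

The study data this package's analyses were designed around (serial
anthropometrics plus skull/shoulder/hip radiographs on healthy children
followed through growth) cannot be redistributed, so this module generates
cohorts with the same statistical structure:

* sex-specific growth-spurt timing (PGA90% age) and adult standing height
  drawn from truncated normals calibrated to the published cohort summary
  (girls 9.7-13.4 yr, mean 11.3; boys 11.7-14.3 yr, mean 13.0; adult heights
  151-175 cm mean 163.4 and 169-183.9 cm mean 177);
* a standing-height trajectory expressed as a fraction of adult height versus
  timing relative to PGA90%, anchored at 85% two years before the spurt peak,
  90% at the peak, and 100% 4.25 years after;
* a T1-S1 trajectory expressed as a fraction of adult T1-S1, whose default
  anchors are the reciprocal of the published body-height-method multiplier
  column (87.1% of adult spine height at PGA90%), or alternatively an exactly
  piecewise-linear trajectory built from the published phase velocities
  (``trajectory_mode="piecewise_linear"``) so velocity estimators can be
  tested against a truth with no interpolation error;
* internally consistent landmark geometry: per-subject constant head height,
  radiographic offsets, and a C1-S1/T1-S1 ratio, with S1 height placed so
  that every reconstruction identity holds exactly when noise is zero;
* independent Gaussian measurement noise on anthropometric and radiographic
  measurements.

Ground truth is returned alongside each subject for parameter-recovery tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.stats import truncnorm

from .cohort import PelvicLandmark, Sex, SubjectSeries, VisitRecord
from .errors import ConfigError
from .reference import BODY_HEIGHT_MULTIPLIERS, TABLE_TIMINGS

#: Default spine-fraction anchors: reciprocal of the published body-height
#: multiplier column, so multiplier recovery is self-consistent.
DEFAULT_SPINE_ANCHORS: tuple[tuple[float, float], ...] = tuple(
    (float(t), float(1.0 / m))
    for t, m in zip(TABLE_TIMINGS, BODY_HEIGHT_MULTIPLIERS)
)

#: Default standing-height fraction anchors (timing yr, fraction of adult).
DEFAULT_HEIGHT_ANCHORS: tuple[tuple[float, float], ...] = (
    (-4.0, 0.79), (-2.0, 0.85), (0.0, 0.90), (4.25, 1.0),
)

#: Default phase velocities, cm/yr, per sex: (childhood, spurt, terminal,
#: mature).  The published mature-phase male slope (-0.12) is clamped to 0
#: here so the simulated truth stays monotone; the estimators downstream must
#: still be able to report negative slopes.
DEFAULT_PHASE_VELOCITIES: dict[str, tuple[float, float, float, float]] = {
    "F": (1.55, 1.75, 0.9, 0.0474),
    "M": (1.14, 2.0, 0.881, -0.12),
}


@dataclass(frozen=True)
class GeneratorConfig:
    """All knobs of the synthetic cohort.

    Defaults are the published study conditions; noise magnitudes are this
    package's own declared choices (the source study never states measurement
    error).
    """

    n_female: int = 35
    n_male: int = 19
    pga_age_mean_f: float = 11.3
    pga_age_range_f: tuple[float, float] = (9.7, 13.4)
    pga_age_mean_m: float = 13.0
    pga_age_range_m: tuple[float, float] = (11.7, 14.3)
    adult_height_mean_f: float = 163.4
    adult_height_range_f: tuple[float, float] = (151.0, 175.0)
    adult_height_mean_m: float = 177.0
    adult_height_range_m: tuple[float, float] = (169.0, 183.9)
    spine_fraction_anchors: tuple[tuple[float, float], ...] = DEFAULT_SPINE_ANCHORS
    height_fraction_anchors: tuple[tuple[float, float], ...] = DEFAULT_HEIGHT_ANCHORS
    adult_t1s1_fraction_of_height: float = 0.27
    c1s1_ratio: float = 0.762
    c1s1_ratio_sd: float = 0.0176
    c1s1_ratio_bounds: tuple[float, float] = (0.70, 0.82)
    eam_c1_offset_mean: float = 1.7
    eam_c1_offset_sd: float = 0.3
    head_height_mean: float = 13.0
    head_height_sd: float = 0.8
    body_spine_beta: float = 1.378
    phase_velocities: dict[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_PHASE_VELOCITIES)
    )
    trajectory_mode: Literal["fraction_curve", "piecewise_linear"] = "fraction_curve"
    noise_sd_anthro: float = 0.3
    noise_sd_radio: float = 0.2
    visit_schedule: Literal["annual", "biannual", "mixed"] = "mixed"
    # per-subject geometric constants (means / sds of once-per-subject draws)
    notch_t1_offset_mean: float = 2.5
    notch_t1_offset_sd: float = 0.4
    symphysis_s1_gap_mean: float = 14.0   # S1 top above symphysis
    symphysis_s1_gap_sd: float = 1.0
    crest_s1_gap_mean: float = -3.0       # S1 top below iliac crest
    crest_s1_gap_sd: float = 0.5
    asis_s1_gap_mean: float = 4.0         # S1 top above ASIS
    asis_s1_gap_sd: float = 0.5
    pelvic_width_spine_fraction: float = 0.6  # adult pelvic width / adult T1-S1
    pelvic_width_spine_fraction_sd: float = 0.03  # between-subject variation
    seed: int = 0

    def validate(self) -> None:
        if self.n_female < 0 or self.n_male < 0:
            raise ConfigError("cohort sizes must be non-negative")
        for mean, (lo, hi), what in (
            (self.pga_age_mean_f, self.pga_age_range_f, "female pga age"),
            (self.pga_age_mean_m, self.pga_age_range_m, "male pga age"),
            (self.adult_height_mean_f, self.adult_height_range_f, "female adult height"),
            (self.adult_height_mean_m, self.adult_height_range_m, "male adult height"),
        ):
            if not lo <= mean <= hi:
                raise ConfigError(f"{what}: range ({lo}, {hi}) must contain mean {mean}")
        for anchors, what in ((self.spine_fraction_anchors, "spine"),
                              (self.height_fraction_anchors, "height")):
            t = [a for a, _ in anchors]
            f = [b for _, b in anchors]
            if any(b <= a for a, b in zip(t, t[1:])):
                raise ConfigError(f"{what} anchors: timings must strictly increase")
            if any(b < a for a, b in zip(f, f[1:])):
                raise ConfigError(f"{what} anchors: fractions must be nondecreasing")
            if not all(0 < x <= 1 for x in f) or abs(f[-1] - 1.0) > 1e-12:
                raise ConfigError(f"{what} anchors: fractions must lie in (0, 1] and end at 1")
        for sd, what in ((self.c1s1_ratio_sd, "c1s1_ratio_sd"),
                         (self.eam_c1_offset_sd, "eam_c1_offset_sd"),
                         (self.head_height_sd, "head_height_sd"),
                         (self.noise_sd_anthro, "noise_sd_anthro"),
                         (self.noise_sd_radio, "noise_sd_radio")):
            if sd < 0:
                raise ConfigError(f"{what} must be >= 0")


@dataclass(frozen=True)
class SubjectTruth:
    """Per-subject ground truth used by parameter-recovery tests."""

    subject_id: str
    sex: Sex
    true_pga_age: float
    true_adult_height: float
    true_adult_t1s1: float
    true_adult_c1s1: float
    true_c1s1_ratio: float
    true_head_height: float
    true_eam_c1_offset: float
    true_notch_t1_offset: float
    true_symphysis_s1_gap: float
    true_crest_s1_gap: float
    true_asis_s1_gap: float
    true_pelvic_width_fraction: float


class FractionCurve:
    """Monotone fraction-of-adult curve over timing relative to PGA90%.

    Piecewise-cubic monotone (PCHIP) through the anchors; constant 1.0 past
    the last anchor; linear continuation below the first anchor at the
    curve's initial (childhood) slope.
    """

    def __init__(self, anchors: Sequence[tuple[float, float]]):
        t = np.array([a for a, _ in anchors], dtype=float)
        f = np.array([b for _, b in anchors], dtype=float)
        self.t0, self.t1 = float(t[0]), float(t[-1])
        self.f0 = float(f[0])
        self._interp = PchipInterpolator(t, f)
        self._slope0 = float(self._interp.derivative()(self.t0))

    def __call__(self, timing):
        scalar = np.ndim(timing) == 0
        t = np.atleast_1d(np.asarray(timing, dtype=float))
        out = np.empty_like(t)
        below = t < self.t0
        above = t >= self.t1
        mid = ~(below | above)
        out[below] = self.f0 + self._slope0 * (t[below] - self.t0)
        out[mid] = self._interp(t[mid])
        out[above] = 1.0
        return float(out[0]) if scalar else out


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lo: float, hi: float, size=None):
    if sd == 0:
        return mean if size is None else np.full(size, mean)
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _subject_rng(seed: int, sex: Sex, index: int) -> np.random.Generator:
    # Per-subject substream keyed by (sex, index): changing the cohort size
    # never shuffles the draws of already-existing subjects.
    sex_code = 0 if sex is Sex.FEMALE else 1
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(sex_code, index)))


def sample_subject_truth(config: GeneratorConfig, sex: Sex,
                         rng: np.random.Generator,
                         subject_id: str = "S000") -> SubjectTruth:
    """Draw one subject's ground truth.

    PGA90% age and adult height are truncated normals with sd = range/4,
    truncated to the published ranges.  Adult T1-S1 is a fixed fraction of
    adult height; adult C1-S1 follows from the subject's own (truncated
    normal) T1-S1/C1-S1 ratio.  Head height and radiographic offsets are
    drawn once and held constant across visits -- cranial height is mature
    well before the ages simulated here.
    """
    config.validate()
    if sex is Sex.FEMALE:
        pga_mean, pga_range = config.pga_age_mean_f, config.pga_age_range_f
        h_mean, h_range = config.adult_height_mean_f, config.adult_height_range_f
    else:
        pga_mean, pga_range = config.pga_age_mean_m, config.pga_age_range_m
        h_mean, h_range = config.adult_height_mean_m, config.adult_height_range_m

    pga = _truncated_normal(rng, pga_mean, (pga_range[1] - pga_range[0]) / 4,
                            *pga_range)
    adult_height = _truncated_normal(rng, h_mean, (h_range[1] - h_range[0]) / 4,
                                     *h_range)
    ratio = _truncated_normal(rng, config.c1s1_ratio, config.c1s1_ratio_sd,
                              *config.c1s1_ratio_bounds)
    adult_t1s1 = config.adult_t1s1_fraction_of_height * adult_height
    adult_c1s1 = adult_t1s1 / ratio
    head = _truncated_normal(rng, config.head_height_mean, config.head_height_sd,
                             config.head_height_mean - 4 * config.head_height_sd - 1e-9,
                             config.head_height_mean + 4 * config.head_height_sd + 1e-9)
    eam = _truncated_normal(rng, config.eam_c1_offset_mean, config.eam_c1_offset_sd,
                            config.eam_c1_offset_mean - 4 * config.eam_c1_offset_sd - 1e-9,
                            config.eam_c1_offset_mean + 4 * config.eam_c1_offset_sd + 1e-9)

    def _geom(mean: float, sd: float) -> float:
        if sd == 0:
            return mean
        return float(rng.normal(mean, sd))

    return SubjectTruth(
        subject_id=subject_id,
        sex=sex,
        true_pga_age=float(pga),
        true_adult_height=float(adult_height),
        true_adult_t1s1=float(adult_t1s1),
        true_adult_c1s1=float(adult_c1s1),
        true_c1s1_ratio=float(ratio),
        true_head_height=float(head),
        true_eam_c1_offset=float(eam),
        true_notch_t1_offset=_geom(config.notch_t1_offset_mean,
                                   config.notch_t1_offset_sd),
        true_symphysis_s1_gap=_geom(config.symphysis_s1_gap_mean,
                                    config.symphysis_s1_gap_sd),
        true_crest_s1_gap=_geom(config.crest_s1_gap_mean, config.crest_s1_gap_sd),
        true_asis_s1_gap=_geom(config.asis_s1_gap_mean, config.asis_s1_gap_sd),
        true_pelvic_width_fraction=_geom(config.pelvic_width_spine_fraction,
                                         config.pelvic_width_spine_fraction_sd),
    )


def height_trajectory(truth: SubjectTruth, config: GeneratorConfig, timing):
    """True standing height (cm) at the given timing(s) relative to PGA90%."""
    curve = FractionCurve(config.height_fraction_anchors)
    return truth.true_adult_height * curve(timing)


def spine_trajectory(truth: SubjectTruth, config: GeneratorConfig, timing):
    """True T1-S1 height (cm) at the given timing(s) relative to PGA90%.

    ``fraction_curve`` mode evaluates the monotone fraction curve;
    ``piecewise_linear`` mode integrates the configured phase velocities
    (mature-phase slope clamped at >= 0 to keep the truth monotone), anchored
    so that T1-S1 at timing +4 equals the subject's adult T1-S1.
    """
    if config.trajectory_mode == "fraction_curve":
        curve = FractionCurve(config.spine_fraction_anchors)
        return truth.true_adult_t1s1 * curve(timing)
    timing = np.asarray(timing, dtype=float)

    v_child, v_spurt, v_term, v_mature = config.phase_velocities[truth.sex.value]
    v_mature = max(0.0, v_mature)
    adult = truth.true_adult_t1s1

    def _value(t: float) -> float:
        if t >= 4.0:
            return adult + v_mature * (t - 4.0)
        if t >= 2.0:
            return adult - v_term * (4.0 - t)
        at2 = adult - 2.0 * v_term
        if t >= -2.0:
            return at2 - v_spurt * (2.0 - t)
        atm2 = at2 - 4.0 * v_spurt
        return atm2 - v_child * (-2.0 - t)

    out = np.vectorize(_value)(timing)
    return out if out.ndim else float(out)


def _schedule(config: GeneratorConfig) -> np.ndarray:
    """Visit timings (yr relative to true PGA90%) from -6 to +5.5."""
    start, stop = -6.0, 5.5
    if config.visit_schedule == "annual":
        t = list(np.arange(start, stop, 1.0))
    elif config.visit_schedule == "biannual":
        t = list(np.arange(start, stop, 0.5))
    elif config.visit_schedule == "mixed":
        # biannual within +/- 2 yr of the spurt peak, annual elsewhere
        t, cur = [], start
        while cur < stop:
            t.append(cur)
            cur += 0.5 if -2.0 <= cur < 2.0 else 1.0
    else:
        raise ConfigError(f"unknown visit_schedule {config.visit_schedule!r}")
    if not math.isclose(t[-1], stop):
        t.append(stop)
    return np.array(t)


def generate_subject(truth: SubjectTruth, config: GeneratorConfig,
                     rng: np.random.Generator) -> SubjectSeries:
    """Simulate one child's visit series from their ground truth.

    Landmark geometry is built top-down so the reconstruction identities hold
    exactly at zero noise: the approximate C1 height (stature minus head
    height) sits one subject-specific C1-S1 span above S1, T1 sits one T1-S1
    span above S1, and each pelvic landmark sits its subject-specific gap
    below/above S1.  Independent Gaussian noise is then added per measurement
    (anthropometric sd ``noise_sd_anthro``, radiographic sd ``noise_sd_radio``).
    """
    timings = _schedule(config)
    ages = truth.true_pga_age + timings
    keep = ages >= 3.0
    timings, ages = timings[keep], ages[keep]

    H = height_trajectory(truth, config, timings)
    t1s1 = spine_trajectory(truth, config, timings)
    c1s1 = t1s1 / truth.true_c1s1_ratio
    c1_height = H - truth.true_head_height
    s1_height = c1_height - c1s1
    t1_height = s1_height + t1s1

    sa, sr = config.noise_sd_anthro, config.noise_sd_radio

    def anthro(x):
        return x + (rng.normal(0, sa, np.shape(x)) if sa > 0 else 0.0)

    def radio(x):
        return x + (rng.normal(0, sr, np.shape(x)) if sr > 0 else 0.0)

    # pelvic proportions genuinely vary between children, so the width-to-
    # spine ratio is a per-subject constant, not a universal one
    pw = truth.true_pelvic_width_fraction * t1s1

    visits = []
    for i in range(len(timings)):
        visits.append(VisitRecord(
            subject_id=truth.subject_id,
            sex=truth.sex,
            age=float(ages[i]),
            standing_height=float(anthro(H[i])),
            sitting_height=float(anthro(0.52 * H[i])),
            h_sternal_notch=float(anthro(t1_height[i] - truth.true_notch_t1_offset)),
            h_symphysis=float(anthro(s1_height[i] - truth.true_symphysis_s1_gap)),
            h_iliac_crest=float(anthro(s1_height[i] - truth.true_crest_s1_gap)),
            h_asis=float(anthro(s1_height[i] - truth.true_asis_s1_gap)),
            head_height=float(anthro(truth.true_head_height)),
            off_notch_T1=float(radio(truth.true_notch_t1_offset)),
            off_pelvis_S1=float(radio(truth.true_symphysis_s1_gap)),
            pelvic_landmark=PelvicLandmark.SYMPHYSIS,
            off_eam_C1=float(radio(truth.true_eam_c1_offset)),
            pelvic_width=float(anthro(pw[i])),
        ))
    return SubjectSeries(truth.subject_id, truth.sex, visits)


def generate_cohort(config: GeneratorConfig
                    ) -> tuple[list[SubjectSeries], list[SubjectTruth]]:
    """Generate the full cohort plus its ground truth. Deterministic in seed."""
    config.validate()
    cohort: list[SubjectSeries] = []
    truths: list[SubjectTruth] = []
    for sex, n, prefix in ((Sex.FEMALE, config.n_female, "F"),
                           (Sex.MALE, config.n_male, "M")):
        for i in range(n):
            rng = _subject_rng(config.seed, sex, i)
            truth = sample_subject_truth(config, sex, rng,
                                         subject_id=f"{prefix}{i + 1:03d}")
            cohort.append(generate_subject(truth, config, rng))
            truths.append(truth)
    return cohort, truths


def generate_beta_pairs(n: int = 500, beta: float = 1.378,
                        noise_sd: float = 0.5,
                        x_range: tuple[float, float] = (30.0, 50.0),
                        rng: np.random.Generator | int | None = None
                        ) -> np.ndarray:
    """Unit-agnostic (spine, body) calibration pairs ``y = beta * x + eps``.

    A dedicated generator for testing the regression-through-origin estimator
    in isolation: a single proportionality constant cannot be embedded in the
    anatomical cohort (standing height and spine height do not stay exactly
    proportional through the spurt), so estimator recovery is checked on pairs
    that satisfy the model by construction.

    Returns an array of shape (n, 2) with columns (x, y).
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    x = rng.uniform(*x_range, size=n)
    y = beta * x + (rng.normal(0.0, noise_sd, size=n) if noise_sd > 0 else 0.0)
    return np.column_stack([x, y])
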