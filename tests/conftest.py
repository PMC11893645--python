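import pytest

from spinegrowth.pipeline import assess_cohort, build_estimate_table
from spinegrowth.simulate import GeneratorConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """Default 54-subject cohort (35 F / 19 M) with default noise, seed 1."""
    cfg = GeneratorConfig(seed=1)
    cohort, truths = generate_cohort(cfg)
    return cfg, cohort, truths


@pytest.fixture(scope="session")
def noise_free_cohort():
    """Cohort with every noise and dispersion source silenced.

    All reconstruction identities hold exactly on this cohort.
    """
    cfg = GeneratorConfig(seed=2, noise_sd_anthro=0.0, noise_sd_radio=0.0,
                          c1s1_ratio_sd=0.0)
    cohort, truths = generate_cohort(cfg)
    return cfg, cohort, truths


@pytest.fixture(scope="session")
def default_estimates(default_cohort):
    """Assessments plus the tidy spine-estimate table for the default cohort."""
    _, cohort, _ = default_cohort
    assessments = assess_cohort(cohort)
    estimates, beta_fit, ratio = build_estimate_table(cohort, assessments)
    return assessments, estimates, beta_fit, ratio
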