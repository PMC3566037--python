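import pytest
from hypothesis import HealthCheck, settings

import capload as cl

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def refs():
    return cl.synthetic_reference_set()


@pytest.fixture(scope="session")
def default_config():
    return cl.calibrate_default_config(n={"male": 3000, "female": 3000})


@pytest.fixture(scope="session")
def small_cohort(refs):
    cfg = cl.calibrate_default_config(n={"male": 400, "female": 400})
    cohort, truth = cl.generate_cohort(cfg, seed=11)
    return cohort, truth, cfg


RECOVERY_SEEDS = list(range(50))
RECOVERY_TERMS = [
    ("model2", "bwz"), ("model2", "cwv"), ("model3", "bwz"), ("model3", "cwv"),
]


@pytest.fixture(scope="session")
def recovery_fits(refs, default_config):
    """Model 2/3 systolic fits on 50 default-config cohorts (n = 3000/sex),
    through the full derived pipeline and on the hidden truth columns."""
    from capload.experiments import growth_model_fits
    return growth_model_fits(default_config, RECOVERY_SEEDS, refs=refs,
                             include_truth_fit=True)
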