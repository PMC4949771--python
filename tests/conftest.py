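import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def four_patient_cohort():
    from dcaw import Cohort

    return Cohort(y=[1, 1, 0, 0], risks={"m": [0.8, 0.4, 0.6, 0.2]})


@pytest.fixture(scope="session")
def svi_cohort():
    """One seeded mid-size cohort from the base generative model."""
    from dcaw import SimulationConfig, simulate_cohort

    cfg = SimulationConfig(n=10000, seed=123)
    return simulate_cohort(cfg, "base")
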