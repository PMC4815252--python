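import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import rareps

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def ref_scenario() -> rareps.SimulationScenario:
    """Reference configuration with both constants calibrated (seed 0)."""
    return rareps.calibrate_scenario(rareps.reference_scenario())


@pytest.fixture(scope="session")
def ref_cohort(ref_scenario) -> rareps.Cohort:
    """One reference cohort of 10,000 subjects."""
    return rareps.generate_cohort(ref_scenario, seed=1)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
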