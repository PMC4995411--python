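import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from canolodge import trials

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def exp1_table():
    """One default irrigation-trial cohort (96 plants, fixed seed)."""
    return trials.simulate_trial(trials.default_config("exp1", seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
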