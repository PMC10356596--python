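import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    database=None,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20220701)


@pytest.fixture
def small_config():
    """A tiny but fully featured synthetic configuration."""
    from octrend import SynthConfig

    return SynthConfig(n_lat=4, n_lon=6, n_years=20, seed=7)
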