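import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture
def small_volume(rng):
    """A 4x4x4x16 random volume with TR = 2 s."""
    from capsfmri.io import TimeSeriesVolume

    return TimeSeriesVolume(rng.normal(size=(4, 4, 4, 16)), 2.0)
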