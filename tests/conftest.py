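import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cvcoupling.io_preprocess import BeatSeries

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def simple_series():
    """Short clean recording with mild variability on all channels."""
    r = np.random.default_rng(7)
    n = 300
    bbi = 800 + 20 * r.standard_normal(n)
    sbp = 120 + 4 * r.standard_normal(n)
    dbp = 70 + 2 * r.standard_normal(n)
    return BeatSeries("S1", "UNKNOWN", bbi, sbp, dbp)
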