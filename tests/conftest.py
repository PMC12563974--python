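import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from efdcomp import CompetitionParams, HistogramSpec

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def spec50() -> HistogramSpec:
    """The study's default binning: 50 ms bins, collapse at 750, outliers at 1500."""
    return HistogramSpec(50.0, 750.0, 1500.0)


@pytest.fixture
def mid_params() -> CompetitionParams:
    """A mid-range parameter point used by several recovery checks."""
    return CompetitionParams(A=1.5, ps=0.25)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
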