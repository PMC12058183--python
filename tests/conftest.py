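import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from irmsim.generation_selection import ExposureParams, hatch_distribution
from irmsim.resistance_scale import FieldCalibration, HillScale

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def scale() -> HillScale:
    return HillScale(z50=900.0)


@pytest.fixture(scope="session")
def cal() -> FieldCalibration:
    return FieldCalibration(phi1=0.48, phi2=0.15)


@pytest.fixture
def exposure() -> ExposureParams:
    return ExposureParams(x=0.7, m=0.5)


@pytest.fixture
def newborns():
    """Standard newborn cohort: mean 100, sigma 30, unit total."""
    return hatch_distribution(100.0, 30.0, n_bins=2001, total=1.0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260923)
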