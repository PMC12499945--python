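import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from stepgrad import DVH, LQParams

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def params():
    """Default tumor LQ parameters: alpha=0.3, beta=0.03, alpha/beta=10."""
    return LQParams()


@pytest.fixture
def hetero_dvh():
    """Two-level heterogeneous DVH: half the volume at 3 Gy, half at 12 Gy."""
    return DVH(bin_dose=[3.0, 12.0], bin_fraction=[0.5, 0.5])


def random_dvh(rng: np.random.Generator, max_bins: int = 40, dose_cap: float = 15.0) -> DVH:
    """Random valid DVH for property tests."""
    m = int(rng.integers(1, max_bins + 1))
    dose = np.sort(rng.uniform(0.0, dose_cap, m))
    dose += np.arange(m) * 1e-6  # enforce strict increase under ties
    frac = rng.dirichlet(np.ones(m))
    return DVH(bin_dose=dose, bin_fraction=frac)
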