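import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow], deadline=None,
)
settings.load_profile("ci")

from incproj.registry import RegistryTable  # noqa: E402


def random_table(rng, n_years=6, n_ages=4, width=5, rate=3e-4,
                 constant_N=False):
    years = 2000 + np.arange(n_years)
    age_lower = 20 + width * np.arange(n_ages)
    if constant_N:
        N = np.full((n_years, n_ages), 8e4)
    else:
        N = rng.uniform(4e4, 1.2e5, size=(n_years, n_ages))
    Y = rng.poisson(rate * N)
    return RegistryTable(years=years, age_lower=age_lower, age_width=width,
                         incidence=Y, population=N)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_table(rng):
    return random_table(rng)
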