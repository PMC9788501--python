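import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import doubleshell as ds

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def band_grid() -> ds.FrequencyGrid:
    """The study sweep: 201 log-spaced points on 500 Hz–300 kHz."""
    return ds.default_grid()


@pytest.fixture(scope="session")
def small_grid() -> ds.FrequencyGrid:
    """Coarse sweep for cheap unit tests."""
    return ds.default_grid(n_points=31)


@pytest.fixture(scope="session")
def truth() -> ds.DSMParams:
    return ds.default_truth()


def random_inbounds_params(rng: np.random.Generator) -> ds.DSMParams:
    """Log-uniform draw from the physical parameter box."""
    b = ds.ParameterBounds()
    r = 10 ** rng.uniform(np.log10(b.r_min), np.log10(b.r_max), 3)
    c = 10 ** rng.uniform(np.log10(b.c_min), np.log10(b.c_max), 2)
    return ds.DSMParams(r[0], r[1], r[2], c[0], c[1])
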