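import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import windkessel_hf as wk

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_grid():
    return wk.ParameterGrid()


@pytest.fixture(scope="session")
def default_surfaces(default_grid):
    """Default 201x201 SBP/DBP surface pair (built once, cached in-process)."""
    return wk.get_surfaces(default_grid)


@pytest.fixture(scope="session")
def small_grid():
    """Coarse grid for tests that rebuild surfaces."""
    return wk.ParameterGrid(n_r=41, n_c=41)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260927)
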