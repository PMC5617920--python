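import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from hoxspring import (
    MorphogenParams,
    Scenario,
    SpringParams,
    default_time_grid,
    wild_type_cluster,
)

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def wt_cluster():
    return wild_type_cluster()


@pytest.fixture
def spring():
    return SpringParams()


@pytest.fixture
def fast_scenario():
    """Default physics on coarser grids: fast enough for many runs per test."""
    return Scenario(n_nodes=101, times=default_time_grid(0.1, n=40))


@pytest.fixture
def unit_gradient_params():
    """lambda = 1 gradient with the source at the anterior end of a long axis."""
    return MorphogenParams(
        diffusion_coeff=1.0,
        decay_rate=1.0,
        source_amplitude=1.0,
        axis_length=5.0,
        source_position=0.0,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20170623)
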