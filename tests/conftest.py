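import numpy as np
import pytest

from cleanfleet import SimConfig, simulate_city
from cleanfleet.weights import lattice_weights


@pytest.fixture(scope="session")
def small_config():
    """A 20x20 city that simulates in well under a second."""
    return SimConfig(nrows=20, ncols=20, n_depots=3, n_routes=40,
                     routes_per_depot_range=(6, 14), route_length_range=(12, 30))


@pytest.fixture(scope="session")
def small_city(small_config):
    return simulate_city(small_config, seed=42)


@pytest.fixture(scope="session")
def default_city():
    return simulate_city(SimConfig(), seed=7)


@pytest.fixture(scope="session")
def w5():
    return lattice_weights(5, 5)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
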