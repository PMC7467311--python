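import numpy as np
import pytest

from pflattice.lattice import default_params, simulate_rise


@pytest.fixture(scope="session")
def gtp_traj():
    """Stress-free single-PF GTP run, long enough for sub-bin minima."""
    return simulate_rise(default_params("GTP"), 1, 50_000, seed=11)


@pytest.fixture(scope="session")
def gdp_traj():
    return simulate_rise(default_params("GDP"), 1, 50_000, seed=12)


@pytest.fixture(scope="session")
def coupled_pair():
    """2-PF GDP run with the default lateral coupling."""
    return simulate_rise(default_params("GDP"), 2, 40_000, seed=21)


@pytest.fixture(scope="session")
def uncoupled_pair():
    """2-PF GDP run with the lateral coupling switched off."""
    return simulate_rise(default_params("GDP", k_lat=0.0), 2, 40_000, seed=21)
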