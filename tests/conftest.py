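import numpy as np
import pytest

from micoconn.phantom import VoxelGrid, make_crossing_phantom, simulate_signal
from micoconn.scheme import make_scheme

FULL_SHELLS = [(500, 30), (1200, 30), (2400, 60), (4000, 60), (6000, 60)]


@pytest.fixture(scope="session")
def full_scheme():
    """The 254-volume multi-shell protocol (5 shells + 14 b=0)."""
    return make_scheme(FULL_SHELLS, n_b0=14, seed=1)


@pytest.fixture(scope="session")
def small_scheme():
    """A light two-shell scheme for fast unit tests."""
    return make_scheme([(1000, 12), (3000, 12)], n_b0=2, seed=2)


@pytest.fixture(scope="session")
def small_phantom(small_scheme):
    """8^3 crossing phantom with noiseless signal (shared, read-only)."""
    grid = VoxelGrid((8, 8, 8))
    tractogram, truth, parc = make_crossing_phantom(
        grid, n_bundles=2, streamlines_per_bundle=8, seed=11
    )
    signal = simulate_signal(tractogram, truth, grid, small_scheme)
    return {
        "grid": grid,
        "tractogram": tractogram,
        "truth": truth,
        "parcellation": parc,
        "signal": signal,
        "scheme": small_scheme,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
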