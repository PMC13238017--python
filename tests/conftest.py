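import numpy as np
import pytest

from kccafmri import VolumeGeometry, simulate_1d


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_geometry():
    return VolumeGeometry.full_grid((6, 6, 6), voxel_size_mm=(2.0, 2.0, 2.0))


@pytest.fixture(scope="session")
def tiny_dataset_1d():
    """A small 1D benchmark instance for fast pipeline tests."""
    return simulate_1d(T=50, Q=400, rho=0.3, seed=7)
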