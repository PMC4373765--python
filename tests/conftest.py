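import numpy as np
import pytest

from tractcompart import phantom
from tractcompart.io import ScalarVolume


@pytest.fixture(scope="session")
def clean_subject():
    """Default-geometry phantom, one partial lesion, zero noise."""
    cfg = phantom.PhantomConfig(seed=7, noise_sigma=0.0)
    return phantom.generate_subject(cfg, subject_id="clean")


@pytest.fixture(scope="session")
def small_config():
    """Coarse, fast phantom geometry for structural tests."""
    return phantom.PhantomConfig(
        seed=3, grid_shape=(64, 64, 64), voxel_size_mm=1.0, n_fibers=100,
        noise_sigma=0.0)


@pytest.fixture(scope="session")
def small_subject(small_config):
    return phantom.generate_subject(small_config, subject_id="small")


@pytest.fixture
def identity_volume():
    """8^3 volume, identity affine, values = x-index (linear field)."""
    data = np.broadcast_to(np.arange(8, dtype=float)[:, None, None],
                           (8, 8, 8)).copy()
    return ScalarVolume(data, np.eye(4))


@pytest.fixture
def constant_volume():
    return ScalarVolume(np.full((8, 8, 8), 0.57), np.eye(4))
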