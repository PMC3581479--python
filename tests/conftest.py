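import numpy as np
import pytest

from ratconn import atlas as atlas_mod


@pytest.fixture(scope="session")
def small_atlas():
    """Compact 4-pair bilateral atlas for fast voxel-level tests."""
    return atlas_mod.make_atlas(grid_shape=(24, 24, 12), n_bilateral=4)


@pytest.fixture(scope="session")
def full_atlas():
    """Default 23-pair atlas."""
    return atlas_mod.make_atlas()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
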