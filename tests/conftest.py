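import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

import petmap as pm
from petmap import phantom


@pytest.fixture
def g16():
    """A small 16^3 grid of 4 mm voxels with a centred origin."""
    return pm.VolumeGrid.centered((16, 16, 16), (4.0, 4.0, 4.0))


@pytest.fixture
def rng():
    return np.random.default_rng(20240601)


@pytest.fixture
def random_volume(g16, rng):
    return pm.BrainVolume(g16, 80.0 + 10.0 * rng.standard_normal(g16.shape))


@pytest.fixture
def full_mask(g16):
    return pm.BrainMask(g16, np.ones(g16.shape, dtype=bool))


# -- a coarse but anatomically complete phantom, shared across tests --------

@pytest.fixture(scope="session")
def small_grid():
    """A 6 mm grid that still contains the whole phantom brain."""
    return pm.VolumeGrid.centered((26, 30, 24), (6.0, 6.0, 6.0))


@pytest.fixture(scope="session")
def small_template(small_grid):
    return phantom.make_template(small_grid)


@pytest.fixture(scope="session")
def small_mask(small_template):
    return phantom.make_gm_wm_mask(small_template)
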