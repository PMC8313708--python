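import numpy as np
import pytest

from bps.doppler import DopplerVolume
from bps.phantom import BranchingConfig, generate_vessel_tree, rasterize_doppler_volume


@pytest.fixture(scope="session")
def vessel_tree():
    return generate_vessel_tree(1, BranchingConfig(depth=4))


@pytest.fixture(scope="session")
def phantom_volume(vessel_tree):
    return rasterize_doppler_volume(vessel_tree, (0.1, 0.1, 0.4), snr=np.inf)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture()
def small_volume(rng):
    return DopplerVolume(rng.random((12, 10, 8)), (0.1, 0.1, 0.2))
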