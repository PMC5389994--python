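import numpy as np
import pytest

from beefield.imaging import RegionMask
from beefield.receptors import AdaptationState
from beefield.spectra import WavelengthGrid, default_receptor_set
from beefield.synth import SceneParams


@pytest.fixture(scope="session")
def grid():
    return WavelengthGrid()


@pytest.fixture(scope="session")
def fine_grid():
    return WavelengthGrid(tuple(np.arange(340.0, 701.0, 1.0)))


@pytest.fixture(scope="session")
def receptors(grid):
    return default_receptor_set(grid)


@pytest.fixture(scope="session")
def adaptation(receptors):
    return AdaptationState.default(receptors)


@pytest.fixture(scope="session")
def scene_params():
    """Smaller-than-default scenes to keep the suite fast."""
    return SceneParams(height=96, width=96, strip_height=12)
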