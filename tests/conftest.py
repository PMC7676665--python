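import numpy as np
import pytest

from cslim.image_io import QuantMap, RgbFrame
from cslim.phantom import PhantomSpec, forward_interferograms, make_phantom


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_phantom():
    """A 256×256 phantom with fibers and cells, deterministic."""
    return make_phantom(PhantomSpec(height_px=256, width_px=256, n_fibers=6, n_cells=4, seed=11))


@pytest.fixture(scope="session")
def small_stack(small_phantom):
    """Noise-free interferogram stack of the small phantom."""
    return forward_interferograms(small_phantom)


@pytest.fixture()
def gradient_map():
    """A smooth ramp map in radians, 64×64."""
    r, c = np.meshgrid(np.arange(64), np.arange(64), indexing="ij")
    return QuantMap((r + c) / 200.0, units="radians")


@pytest.fixture()
def white_frame():
    return RgbFrame(np.ones((32, 32, 3)))
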