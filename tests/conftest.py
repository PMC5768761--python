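import numpy as np
import pytest

from qpcdiff import OpticalConfig, make_phantom


@pytest.fixture
def optics():
    return OpticalConfig()


@pytest.fixture
def small_phantom():
    """A few progenitor cells on a small grid, fixed seed."""
    return make_phantom(1, {"progenitor": 4}, grid_shape=(256, 256), seed=11)


@pytest.fixture
def textured_image():
    """Deterministic textured image for focus / entropy tests.

    A large-scale ramp fixes the global gray-level range while fine noise
    provides the focus-sensitive texture, so local histograms stay well
    below the bin-saturation ceiling and respond to blur.
    """
    rng = np.random.default_rng(42)
    yy, xx = np.mgrid[0:96, 0:96]
    return 10.0 * (xx + yy) / 192.0 + rng.random((96, 96))
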