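import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def concentric_masks():
    """Concentric disk nucleus (r=20) and cell (r=100) on a 256x256 grid."""
    yy, xx = np.mgrid[0:256, 0:256]
    rho2 = (xx - 128) ** 2 + (yy - 128) ** 2
    return rho2 <= 100**2, rho2 <= 20**2
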