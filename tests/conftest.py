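import numpy as np
import pytest

from demicell.synthdata import FWHM_TO_SIGMA


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def render_gaussian(shape, x, y, fwhm, h, b=0.0):
    """Independent noiseless renderer used as a fixture-level constructor."""
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]].astype(float)
    sigma = fwhm * FWHM_TO_SIGMA
    return h * np.exp(-((cc - x) ** 2 + (rr - y) ** 2) / (2 * sigma**2)) + b


@pytest.fixture
def gaussian_image():
    return render_gaussian
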