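import numpy as np
import pytest

from leafseg import LeafSpec, make_leaf


@pytest.fixture()
def two_region_image():
    """Noise-free piecewise-constant image: left half 60, right half 200."""
    img = np.full((60, 80), 60, dtype=np.uint8)
    img[:, 40:] = 200
    truth = (img == 200).astype(np.uint8)
    return img, truth


@pytest.fixture()
def small_leaf():
    """A quick 160-px leaf fixture with moderate noise."""
    img, mask = make_leaf(LeafSpec(side=160, noise_sigma=5.0, seed=0))
    return img, mask
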