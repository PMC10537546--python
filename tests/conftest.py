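import numpy as np
import pytest

from mpshape.labeling import label_components, sort_and_select_largest


def largest_region(mask):
    """Selected (largest) region of a binary mask."""
    _, regions = label_components(mask)
    return sort_and_select_largest(regions)


@pytest.fixture
def block_5x5():
    mask = np.zeros((7, 7), dtype=np.uint8)
    mask[1:6, 1:6] = 1
    return mask


@pytest.fixture
def block_5x5_hole(block_5x5):
    mask = block_5x5.copy()
    mask[3, 3] = 0
    return mask


@pytest.fixture
def single_pixel():
    mask = np.zeros((3, 3), dtype=np.uint8)
    mask[1, 1] = 1
    return mask


@pytest.fixture
def annulus():
    """Ring: 9x9 disk-ish square with a 3x3 hole."""
    mask = np.zeros((11, 11), dtype=np.uint8)
    mask[1:10, 1:10] = 1
    mask[4:7, 4:7] = 0
    return mask
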