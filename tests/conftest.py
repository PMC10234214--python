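import numpy as np
import pytest


def render_disks(shape, disks, fg=60, bg=200):
    """Independent rasteriser: paint filled disks (row, col, r) with
    pixel-center membership dist <= r. Used as the oracle-side renderer."""
    img = np.full(shape, bg, dtype=np.uint8)
    rows, cols = np.mgrid[0 : shape[0], 0 : shape[1]]
    for r0, c0, r in disks:
        img[(rows - r0) ** 2 + (cols - c0) ** 2 <= r * r] = fg
    return img


@pytest.fixture
def disk_image():
    return render_disks


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
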