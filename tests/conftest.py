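import numpy as np
import pytest

from lycheevision.segmentation import extract_regions


def disc_mask(shape, cy, cx, r, base=None):
    """Pixel-center rasterized disc painted onto a fresh (or given) canvas.

    Uses the inclusive inequality (dist <= r), so the pixel count tracks
    pi * r**2 closely (boundary pixels at exactly distance r belong in).
    """
    m = np.zeros(shape, dtype=bool) if base is None else base
    ys, xs = np.mgrid[0 : shape[0], 0 : shape[1]]
    m |= (xs - cx) ** 2 + (ys - cy) ** 2 <= r * r
    return m


def single_region(mask):
    regions = extract_regions(mask)
    assert len(regions) == 1, f"expected one region, got {len(regions)}"
    return regions[0]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
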