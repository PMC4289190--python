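import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_patch(rng):
    """A random 16x16x3 patch with non-trivial per-channel spread."""
    return rng.uniform(0, 255, size=(16, 16, 3))


def make_ellipse_image(
    canvas=256, center=(128, 128), radii=(60, 25), value=60, background=220
):
    """A dark ellipse on a bright background, plus its ground-truth mask."""
    rr, cc = np.mgrid[0:canvas, 0:canvas]
    mask = ((rr - center[0]) / radii[0]) ** 2 + ((cc - center[1]) / radii[1]) ** 2 <= 1
    img = np.full((canvas, canvas, 3), background, dtype=np.uint8)
    img[mask] = value
    return img, mask
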