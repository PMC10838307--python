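import numpy as np
import pytest


def make_ellipse_mask(a: float, b: float, angle: float = 0.0, size: int = 160) -> np.ndarray:
    """Rasterized ellipse with semi-axes a, b (pixels) centered in the image."""
    c = (size - 1) / 2.0
    rr, cc = np.mgrid[0:size, 0:size].astype(float)
    dy, dx = rr - c, cc - c
    u = (dx * np.cos(angle) + dy * np.sin(angle)) / a
    v = (-dx * np.sin(angle) + dy * np.cos(angle)) / b
    return np.hypot(u, v) <= 1.0


@pytest.fixture
def ellipse_mask():
    return make_ellipse_mask


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
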