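import numpy as np
import pytest

from gastroquant.profiles import ImageStack


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def make_stack(data, frame_interval=2.0, pixel_size=0.1, z_spacing=1.0):
    """Wrap an array (adding T/Z axes as needed) into an ImageStack."""
    data = np.asarray(data, dtype=float)
    if data.ndim == 2:
        data = data[None, None]
    elif data.ndim == 3:
        data = data[:, None]
    return ImageStack(data, frame_interval, pixel_size, z_spacing)


def gaussian_spot(shape, cx, cy, sigma=1.5, amp=100.0):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]].astype(float)
    return amp * np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * sigma**2))


def bilinear(image, x, y):
    """Reference bilinear interpolation at pixel-centered (x, y), edge-clamped."""
    h, w = image.shape
    x = min(max(x, 0.0), w - 1.0)
    y = min(max(y, 0.0), h - 1.0)
    x0, y0 = int(np.floor(x)), int(np.floor(y))
    x1, y1 = min(x0 + 1, w - 1), min(y0 + 1, h - 1)
    fx, fy = x - x0, y - y0
    return (
        image[y0, x0] * (1 - fx) * (1 - fy)
        + image[y0, x1] * fx * (1 - fy)
        + image[y1, x0] * (1 - fx) * fy
        + image[y1, x1] * fx * fy
    )
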