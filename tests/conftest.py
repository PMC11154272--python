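import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True,
                          max_examples=25)
settings.load_profile("ci")

from dualct.geometry import ImageGrid, ScanGeometry, default_pixel_size


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_geom():
    """Scaled-down scanner: 64 views over 360 deg, 80-element detector."""
    return ScanGeometry(n_views_full=64, n_detectors=80, detector_pitch=2.0)


def make_disk(image_size, pixel_size, radius_mm, mu, supersample=8,
              center=(0.0, 0.0)):
    """Anti-aliased uniform disk phantom (coverage-weighted edge pixels)."""
    n = image_size * supersample
    xs = (np.arange(n) - (n - 1) / 2.0) * (pixel_size / supersample)
    X = xs[None, :]
    Y = xs[:, None]
    inside = ((X - center[0]) ** 2 + (Y - center[1]) ** 2) <= radius_mm ** 2
    img = inside.astype(np.float64) * mu
    img = img.reshape(image_size, supersample, image_size,
                      supersample).mean(axis=(1, 3))
    return ImageGrid(img.astype(np.float32), pixel_size)


@pytest.fixture
def disk_phantom(small_geom):
    px = default_pixel_size(small_geom, 64)
    return make_disk(64, px, radius_mm=20.0, mu=0.02)
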