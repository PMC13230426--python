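import numpy as np
import pytest

from profcorrect.grids import BinaryMask, Volume


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_mask_pair(rng, shape=(8, 8, 8), spacing=(1.0, 1.0, 1.0), p=0.5):
    a = BinaryMask((rng.random(shape) < p).astype(np.uint8), spacing)
    b = BinaryMask((rng.random(shape) < p).astype(np.uint8), spacing)
    return a, b


def ball_mask(shape=(16, 16, 16), spacing=(1.0, 1.0, 1.0), center=None, radius_mm=5.0):
    """Voxelized ball; the workhorse non-trivial geometric fixture."""
    if center is None:
        center = [(n - 1) * s / 2.0 for n, s in zip(shape, spacing)]
    axes = [np.arange(n) * s for n, s in zip(shape, spacing)]
    zz, yy, xx = np.meshgrid(*axes, indexing="ij")
    d2 = (zz - center[0]) ** 2 + (yy - center[1]) ** 2 + (xx - center[2]) ** 2
    return BinaryMask((d2 <= radius_mm ** 2).astype(np.uint8), spacing)


@pytest.fixture
def small_volume(rng):
    return Volume(rng.normal(50.0, 10.0, (12, 12, 12)).astype(np.float32),
                  spacing=(2.0, 1.0, 1.0))
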