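import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_volume(rng):
    """An 8x8x8 HU-valued volume with plausible CT range."""
    from corovox.imaging_io import CTVolume

    voxels = rng.normal(40.0, 200.0, size=(8, 8, 8)).astype(np.float32)
    return CTVolume(voxels, spacing=(0.45, 0.4, 0.4))


def random_mask(rng, shape=(12, 12, 12), p=0.2):
    """A random non-empty binary mask."""
    m = (rng.random(shape) < p).astype(np.uint8)
    if not m.any():
        m[tuple(s // 2 for s in shape)] = 1
    return m
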