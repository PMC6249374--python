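import numpy as np
import pytest

from mtlatlas.volume import LabeledVolume, default_affine


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_grid():
    """A 24^3 1 mm grid centered near the origin."""
    return (24, 24, 24), default_affine((-12.0, -12.0, -12.0))


def make_volume(indices, shape=(24, 24, 24), translation=(-12.0, -12.0, -12.0)):
    """Binary LabeledVolume with the given voxel indices set."""
    data = np.zeros(shape, dtype=np.uint8)
    for idx in indices:
        data[tuple(idx)] = 1
    return LabeledVolume(data, default_affine(translation))
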