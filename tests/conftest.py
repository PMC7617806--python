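import numpy as np
import pytest

from colocq import DoGParams, SegmentationMask, VoxelGrid


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def default_params():
    return DoGParams()


def random_grid(rng, shape, lo=0.0, hi=100.0):
    """Random non-negative raw stack as a VoxelGrid."""
    return VoxelGrid(rng.uniform(lo, hi, size=shape))


def random_mask(rng, shape, p=0.3, label=""):
    return SegmentationMask(rng.random(shape) < p, source_channel=label, threshold_used=0.0)
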