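import numpy as np
import pytest

from acctex.volumes import VOI, Volume


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_region(rng, max_side=8, min_voxels=12):
    """A random small volume/VOI pair for oracle comparisons."""
    shape = tuple(int(s) for s in rng.integers(2, max_side + 1, 3))
    mask = rng.random(shape) < 0.7
    if mask.sum() < min_voxels:
        mask[:] = True
    data = rng.normal(60.0, 40.0, shape).round(1)
    vol = Volume(data, spacing=(1.5, 0.7, 0.7), phase="venous")
    return vol, VOI(mask=mask, kind="tumour-gross")


@pytest.fixture
def region_factory(rng):
    return lambda **kw: random_region(rng, **kw)
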