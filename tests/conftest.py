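import numpy as np
import pytest

from petrad.imaging import DiscretizationConfig, LesionROI, PETVolume


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def default_cfg():
    return DiscretizationConfig()


def make_volume(values, spacing=(3.0, 3.0, 3.0)):
    return PETVolume(voxels=np.asarray(values, dtype=float), spacing=spacing)


def make_roi(mask, **kwargs):
    kwargs.setdefault("lesion_id", "test")
    return LesionROI(mask=np.asarray(mask, dtype=bool), **kwargs)


@pytest.fixture
def random_volume_roi(rng):
    """A 10x10x10 random volume with a random ~50% mask."""
    vol = make_volume(rng.uniform(0, 55, size=(10, 10, 10)))
    mask = rng.random((10, 10, 10)) < 0.5
    mask.flat[0] = True  # never empty
    return vol, make_roi(mask)
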