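import numpy as np
import pytest

from veinwidth import PipelineConfig, degrade, make_vessel
from veinwidth.skeleton import SkeletonMap


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def straight7():
    """Noiseless straight vessel of width 7 in a 100x100 frame."""
    return make_vessel("straight", width=7)


@pytest.fixture
def degraded7():
    """Width-7 straight vessel with blur 1.0 and noise 8."""
    return degrade(make_vessel("straight", width=7), blur_sigma=1.0,
                   noise_sigma=8.0, seed=7)


@pytest.fixture
def default_config():
    return PipelineConfig()


def centerline_skeleton(truth) -> SkeletonMap:
    """SkeletonMap built from a phantom's ground-truth centerline."""
    grid = np.zeros_like(truth.mask, dtype=bool)
    for r, c in truth.centerline:
        grid[r, c] = True
    return SkeletonMap(pixels=grid, points=list(truth.centerline))
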