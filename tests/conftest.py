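import numpy as np
import pytest
from hypothesis import settings, HealthCheck

from brainstemnm.core import ImageVolume, RoiMask

settings.register_profile(
    "ci", derandomize=True, max_examples=25, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_volume(data, voxel_size=(1.0, 1.0, 1.0), grid_id="g"):
    return ImageVolume(np.asarray(data, dtype=float), voxel_size, grid_id)


def block_mask(label, i0, i1, j0, j1, k0, k1, grid_id="g", side="none"):
    ii, jj, kk = np.meshgrid(np.arange(i0, i1), np.arange(j0, j1), np.arange(k0, k1), indexing="ij")
    vox = np.column_stack([ii.ravel(), jj.ravel(), kk.ravel()])
    return RoiMask(label, vox, grid_id, side)
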