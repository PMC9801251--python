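import numpy as np
import pytest

from vtamap.synthetic import PhantomSpec
from vtamap.volume import Mask, VolumeGrid


@pytest.fixture(scope="session")
def noiseless_phantom():
    """Default-geometry phantom without noise, shared across tests."""
    from vtamap.synthetic import make_phantom

    spec = PhantomSpec(noise_sd=0.0, seed=42)
    mt, non_mt, truth = make_phantom(spec)
    return spec, mt, non_mt, truth


@pytest.fixture(scope="session")
def noisy_phantom():
    from vtamap.synthetic import make_phantom

    spec = PhantomSpec(noise_sd=0.01, seed=43)
    mt, non_mt, truth = make_phantom(spec)
    return spec, mt, non_mt, truth


@pytest.fixture
def small_grid():
    """Tiny grid helpers for mask arithmetic tests."""

    def build(arr, voxel=0.4):
        return Mask(np.asarray(arr, dtype=bool), (voxel,) * 3)

    return build


@pytest.fixture
def small_volume():
    def build(arr, voxel=0.4):
        return VolumeGrid(np.asarray(arr, dtype=float), (voxel,) * 3)

    return build
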