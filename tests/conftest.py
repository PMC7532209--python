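import numpy as np
import pytest

from roqa.volume_io import IntensityVolume


def voxelized_ellipsoid(
    semi_axes, spacing=(1.0, 1.0, 1.0), rot=None, pad=3
) -> np.ndarray:
    """Boolean mask of an ellipsoid sampled at voxel centers."""
    semi = np.asarray(semi_axes, dtype=float)
    spacing = np.asarray(spacing, dtype=float)
    if rot is None:
        rot = np.eye(3)
    half = semi.max() / spacing + pad
    shape = (2 * np.ceil(half) + 1).astype(int)
    center = (shape * spacing) / 2.0
    grids = np.meshgrid(
        *[(np.arange(n) + 0.5) * s - c for n, s, c in zip(shape, spacing, center)],
        indexing="ij",
    )
    rel = np.stack(grids, axis=-1) @ rot
    r2 = np.sum((rel / semi) ** 2, axis=-1)
    return r2 <= 1.0


@pytest.fixture
def sphere_mask():
    return voxelized_ellipsoid((20, 20, 20))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_volume(rng):
    data = rng.integers(0, 65535, size=(16, 16, 16), dtype=np.uint16)
    return IntensityVolume(data, (1.0, 1.0, 1.0))
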