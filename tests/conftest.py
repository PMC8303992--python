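import numpy as np
import pytest

from fmisodyn import BinaryMask, PETVolume


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def make_volume(values, spacing=(2.0, 2.0, 2.0), time_point="W0"):
    return PETVolume(np.asarray(values, dtype=float), spacing, time_point=time_point)


def make_mask(values, spacing=(2.0, 2.0, 2.0), role="HSV"):
    return BinaryMask(np.asarray(values, dtype=bool), spacing, role=role)


def sphere_mask(shape, center, radius, spacing=(2.0, 2.0, 2.0), role="HSV"):
    """Voxel-index sphere (radius in voxels) used to build small phantoms."""
    grids = np.ogrid[tuple(slice(0, n) for n in shape)]
    d2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    return make_mask(d2 <= radius ** 2, spacing=spacing, role=role)


@pytest.fixture
def small_sphere():
    return sphere_mask((16, 16, 16), (8, 8, 8), 4.0)
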