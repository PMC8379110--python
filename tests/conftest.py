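import numpy as np
import pytest

from ablamargin.grids import VoxelGrid
from ablamargin.phantoms import SpherePhantomSpec, make_sphere_phantom


def brute_force_distance_map(mask: np.ndarray, spacing) -> np.ndarray:
    """All-pairs voxel-center Euclidean distances to the foreground.

    Independent oracle for the EDT-based distance map: O(V * F), usable
    only on small grids.
    """
    mask = np.asarray(mask, dtype=bool)
    spacing = np.asarray(spacing, dtype=float)
    fg = np.argwhere(mask) * spacing
    all_idx = np.argwhere(np.ones_like(mask)) * spacing
    d2 = ((all_idx[:, None, :] - fg[None, :, :]) ** 2).sum(axis=2)
    return np.sqrt(d2.min(axis=1)).reshape(mask.shape)


def random_grid(rng, shape=(10, 10, 10), spacing=(1.0, 1.0, 1.0), p=0.1) -> VoxelGrid:
    return VoxelGrid(rng.random(shape) < p, spacing)


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture(scope="session")
def concentric_10_12():
    """Tumor radius 10 mm, ablation radius 12 mm, 1-mm isotropic voxels."""
    return make_sphere_phantom(
        SpherePhantomSpec(tumor_radius=10, ablation_radius=12, pad=12)
    )
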