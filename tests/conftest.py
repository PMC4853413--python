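"""Shared fixtures: small phantom specs with hand-computable degree
structure."""

import numpy as np
import pytest

from fcdmap import NetworkSpec, PhantomSpec, VoxelGrid, make_phantom_grid


def block(x0, y0, z0, dx, dy, dz):
    return np.array(
        [(i, j, k)
         for i in range(x0, x0 + dx)
         for j in range(y0, y0 + dy)
         for k in range(z0, z0 + dz)]
    )


@pytest.fixture
def small_grid() -> VoxelGrid:
    """Even-width 8x6x6 grid, 2 mm voxels, centered affine: 4 planes left,
    4 right, no midline."""
    affine = np.diag([2.0, 2.0, 2.0, 1.0])
    affine[:3, 3] = [-7.0, -5.0, -5.0]
    return VoxelGrid(mask=np.ones((8, 6, 6), dtype=bool), affine=affine)


@pytest.fixture
def homotopic_spec() -> PhantomSpec:
    """One homotopic network of 15 + 15 mirrored voxels, coupling 0.8:
    each member voxel has 15 contralateral and 14 ipsilateral partners."""
    return PhantomSpec(
        grid_shape=(12, 10, 10),
        networks=[
            NetworkSpec("homotopic", block(1, 2, 4, 3, 5, 1), 0.8, "homotopic")
        ],
        n_timepoints=200,
    )


@pytest.fixture
def unilateral_spec() -> PhantomSpec:
    """One left-hemisphere network of 30 voxels, coupling 0.8: each member
    has 29 ipsilateral partners and no contralateral ones."""
    return PhantomSpec(
        grid_shape=(12, 10, 10),
        networks=[
            NetworkSpec("left_only", block(1, 2, 6, 3, 5, 2), 0.8, "unilateral-left")
        ],
        n_timepoints=200,
    )


@pytest.fixture
def null_spec() -> PhantomSpec:
    """All-noise phantom: one network with zero coupling on a small grid."""
    return PhantomSpec(
        grid_shape=(8, 8, 8),
        networks=[NetworkSpec("silent", block(1, 2, 2, 2, 3, 3), 0.0, "homotopic")],
        n_timepoints=200,
    )
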