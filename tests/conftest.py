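import itertools

import numpy as np
import pytest

from microsol.imaging_io import BinaryMask, ImageStack, VoxelSpacing


@pytest.fixture
def iso_spacing() -> VoxelSpacing:
    """Isotropic 1 um voxels, convenient for geometric reasoning."""
    return VoxelSpacing(dx=1.0, dy=1.0, dz=1.0)


@pytest.fixture
def confocal_spacing() -> VoxelSpacing:
    """Anisotropic spacing of the modeled acquisition (780 um / 512 px, 2.5 um z)."""
    return VoxelSpacing(dx=780 / 512, dy=780 / 512, dz=2.5)


def make_stack(voxels, spacing=None, name="test") -> ImageStack:
    return ImageStack(
        voxels=np.asarray(voxels, dtype=np.float32),
        spacing=spacing or VoxelSpacing(dx=1.0, dy=1.0, dz=1.0),
        name=name,
    )


def make_mask(voxels, spacing=None) -> BinaryMask:
    return BinaryMask(
        voxels=np.asarray(voxels, dtype=bool),
        spacing=spacing or VoxelSpacing(dx=1.0, dy=1.0, dz=1.0),
    )


def filled_cuboid(nz, ny, nx) -> np.ndarray:
    """All lattice points of an nz x ny x nx box as an (n, 3) array."""
    return np.array(list(itertools.product(range(nz), range(ny), range(nx))))


def random_blob(rng: np.random.Generator, n_steps: int = 120) -> np.ndarray:
    """Random connected voxel set grown by a lattice random walk."""
    pts = {(0, 0, 0)}
    p = np.zeros(3, dtype=int)
    moves = np.array(list(itertools.product([-1, 0, 1], repeat=3)))
    for _ in range(n_steps):
        p = p + moves[rng.integers(len(moves))]
        pts.add(tuple(p))
    return np.array(sorted(pts))
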