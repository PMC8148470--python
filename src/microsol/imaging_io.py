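"""Image-stack containers and TIFF / CSV input-output.

All volumes use ``(z, y, x)`` axis order, matching the page-major layout of
multi-page TIFF files.  Voxel spacing is always supplied by the caller (or a
config file), never parsed from TIFF metadata: metadata dialects are too
unreliable, and the axial step of the acquisitions this package models is
known (2.5 um between confocal planes).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "VoxelSpacing",
    "ImageStack",
    "BinaryMask",
    "ImageIOError",
    "UnreadableFileError",
    "MultichannelError",
    "InconsistentPagesError",
    "read_stack",
    "write_stack",
    "write_cell_table",
    "write_eye_table",
    "CELL_TABLE_COLUMNS",
]


class ImageIOError(Exception):
    """Base class for image input/output failures."""


class UnreadableFileError(ImageIOError):
    """The path does not exist or is not a TIFF this package can read."""


class MultichannelError(ImageIOError):
    """RGB / multichannel TIFFs are rejected, not silently reduced.

    The quantifications this package implements operate on single-channel
    stainings; collapsing channels implicitly would hide a user error.
    """


class InconsistentPagesError(ImageIOError):
    """TIFF pages differ in shape and cannot form a rectangular stack."""


@dataclass(frozen=True)
class VoxelSpacing:
    """Physical voxel size in micrometres along each axis.

    ``dz`` defaults to 2.5 um, the axial step between confocal planes used
    throughout; ``dx``/``dy`` depend on objective and sensor and must be
    supplied (e.g. field width in um divided by pixels per side).
    """

    dx: float
    dy: float
    dz: float = 2.5

    def __post_init__(self) -> None:
        for name in ("dx", "dy", "dz"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"VoxelSpacing.{name} must be finite and > 0, got {v!r}")

    @property
    def voxel_volume_um3(self) -> float:
        return self.dx * self.dy * self.dz

    def as_zyx(self) -> tuple[float, float, float]:
        return (self.dz, self.dy, self.dx)


@dataclass
class ImageStack:
    """A 3D grayscale intensity volume with physical voxel spacing.

    ``voxels`` is float32 in ``(z, y, x)`` order; intensities are finite and
    non-negative (integer TIFF data is promoted to float without rescaling).
    """

    voxels: np.ndarray
    spacing: VoxelSpacing
    name: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.voxels, dtype=np.float32)
        if v.ndim != 3 or min(v.shape) < 1:
            raise ValueError(f"stack must be 3D (z, y, x), got shape {v.shape}")
        if not np.all(np.isfinite(v)):
            raise ValueError("stack intensities must be finite")
        if v.min() < 0:
            raise ValueError("stack intensities must be >= 0")
        self.voxels = v

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


@dataclass
class BinaryMask:
    """A boolean volume sharing the geometry of the stack it derives from."""

    voxels: np.ndarray
    spacing: VoxelSpacing

    def __post_init__(self) -> None:
        v = np.asarray(self.voxels)
        if v.dtype != bool:
            raise ValueError(f"mask voxels must be boolean, got dtype {v.dtype}")
        if v.ndim != 3:
            raise ValueError(f"mask must be 3D (z, y, x), got shape {v.shape}")
        self.voxels = v

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


def read_stack(path: str | Path, spacing: VoxelSpacing, name: str | None = None) -> ImageStack:
    """Read a multi-page grayscale TIFF as an :class:`ImageStack`.

    Pages become z-slices in file order; a single-page TIFF yields shape
    ``(1, H, W)``.  Integer intensities are promoted to float32 without
    rescaling.  RGB/multichannel files and files whose pages differ in
    shape raise distinct errors.
    """
    path = Path(path)
    try:
        tf = tifffile.TiffFile(path)
    except (FileNotFoundError, OSError, ValueError) as exc:
        raise UnreadableFileError(f"cannot read TIFF {path}: {exc}") from exc
    with tf:
        pages = list(tf.pages)
        if not pages:
            raise UnreadableFileError(f"{path} contains no image pages")
        arrays = []
        for page in pages:
            if getattr(page, "samplesperpixel", 1) > 1:
                raise MultichannelError(
                    f"{path} has {page.samplesperpixel} samples per pixel; "
                    "only single-channel grayscale stacks are supported"
                )
            arr = page.asarray()
            if arr.ndim != 2:
                raise MultichannelError(f"{path}: page is not a 2D grayscale plane (shape {arr.shape})")
            arrays.append(arr)
        shapes = {a.shape for a in arrays}
        if len(shapes) > 1:
            raise InconsistentPagesError(f"{path}: pages differ in shape: {sorted(shapes)}")
    voxels = np.stack(arrays).astype(np.float32)
    return ImageStack(voxels=voxels, spacing=spacing, name=name if name is not None else path.stem)


def write_stack(stack: ImageStack, path: str | Path) -> None:
    """Write a stack as a multi-page float32 TIFF.

    ``read_stack(write_stack(s))`` is the identity on voxel values and shape.
    """
    path = Path(path)
    if not path.parent.is_dir():
        raise ImageIOError(f"parent directory does not exist: {path.parent}")
    tifffile.imwrite(path, stack.voxels, photometric="minisblack")


CELL_TABLE_COLUMNS = (
    "cell_id",
    "lesion_id",
    "eye_id",
    "voxel_count",
    "volume_um3",
    "convex_voxel_count",
    "solidity",
    "border_touching",
)


def write_cell_table(cells: Sequence, path: str | Path) -> None:
    """Write per-cell morphology records to CSV with a stable column order.

    Floats are printed with 9 significant digits so the file round-trips to
    well beyond measurement precision; decimal separator is always '.'.
    """
    rows = [{c: getattr(cell, c) for c in CELL_TABLE_COLUMNS} for cell in cells]
    df = pd.DataFrame(rows, columns=list(CELL_TABLE_COLUMNS))
    df.to_csv(path, index=False, float_format="%.9g")


def write_eye_table(eyes: Iterable, path: str | Path) -> None:
    """Write per-eye aggregates (eye_id, n_cells, mean_solidity) to CSV."""
    cols = ("eye_id", "n_cells", "mean_solidity")
    rows = [{c: getattr(e, c) for c in cols} for e in eyes]
    pd.DataFrame(rows, columns=list(cols)).to_csv(path, index=False, float_format="%.9g")
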