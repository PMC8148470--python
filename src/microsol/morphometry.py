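"""Tridimensional solidity: voxel count over convex-hull lattice-point count.

Solidity of a segmented cell is the ratio between its volume and its convex
volume, where the convex hull is the smallest region that is convex and
contains the cell.  Both volumes are realized as lattice-point counts: the
object's voxel count, and the number of lattice points inside or on the
convex hull of the object's voxel centers.  This discretization guarantees
solidity == 1 exactly for digitally convex objects and <= 1 always (a
continuous hull volume of voxel centers would undercount and push convex
objects above 1).

Compact, amoeboid cells (activated microglia) score near 1; ramified cells
with thin processes score well below 1, because the processes span a hull
volume they do not fill.

Because the count is taken on the integer lattice, solidity is independent
of the physical voxel spacing and invariant under axis-aligned translation,
90-degree rotation and axis permutation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage as ndi
from scipy.spatial import ConvexHull, QhullError

from .imaging_io import VoxelSpacing
from .segment3d import LabelVolume, flag_border_cells

__all__ = [
    "CellMorphology",
    "EyeSolidity",
    "convex_voxel_count",
    "solidity",
    "measure_cells",
    "mean_solidity_per_eye",
]

# Facet inequalities are satisfied with this slack so that lattice points
# lying exactly on the hull boundary count as inside ("contains the
# original region").
HULL_TOL = 1e-9
# Rank decisions and affine-subspace membership use a looser tolerance:
# SVD residuals on integer coordinates are ~1e-12, while genuinely
# off-subspace lattice points sit at distances far above 1e-6.
PLANE_TOL = 1e-6


@dataclass(frozen=True)
class CellMorphology:
    """Per-cell morphology record."""

    cell_id: int
    lesion_id: str
    eye_id: str
    voxel_count: int
    volume_um3: float
    convex_voxel_count: int
    solidity: float
    border_touching: bool

    def __post_init__(self) -> None:
        if not (1 <= self.voxel_count <= self.convex_voxel_count):
            raise ValueError("voxel_count must satisfy 1 <= voxel_count <= convex_voxel_count")
        if not (0 < self.solidity <= 1):
            raise ValueError("solidity must lie in (0, 1]")


@dataclass(frozen=True)
class EyeSolidity:
    """Mean solidity over all eligible cells of one eye."""

    eye_id: str
    n_cells: int
    mean_solidity: float


def _as_points(cell_voxels: Iterable[tuple[int, int, int]] | np.ndarray) -> np.ndarray:
    pts = np.asarray(sorted(map(tuple, cell_voxels)) if not isinstance(cell_voxels, np.ndarray) else cell_voxels)
    if pts.size == 0:
        raise ValueError("cell has no voxels")
    pts = pts.reshape(-1, 3).astype(np.float64)
    return pts


def _bbox_lattice(pts: np.ndarray) -> np.ndarray:
    lo = np.floor(pts.min(axis=0)).astype(int)
    hi = np.ceil(pts.max(axis=0)).astype(int)
    grids = np.meshgrid(*(np.arange(a, b + 1) for a, b in zip(lo, hi)), indexing="ij")
    return np.stack([g.ravel() for g in grids], axis=1).astype(np.float64)


def convex_voxel_count(
    cell_voxels: Iterable[tuple[int, int, int]] | np.ndarray,
    spacing: VoxelSpacing | None = None,
) -> int:
    """Number of lattice points inside or on the convex hull of the voxels.

    Degenerate voxel sets (single point, collinear, coplanar) are handled by
    computing the hull in their affine span: lattice points of the bounding
    box are first filtered to the span, then tested against the
    lower-dimensional hull.  Always >= the voxel count.

    ``spacing`` is accepted for interface symmetry but does not enter the
    count: hulls are taken on the integer lattice, so the ratio is a pure
    shape descriptor independent of voxel anisotropy.
    """
    pts = _as_points(cell_voxels)
    n = len(pts)
    if n == 1:
        return 1

    centered = pts - pts.mean(axis=0)
    # rank of the affine span via singular values
    sv = np.linalg.svd(centered, compute_uv=False)
    scale = max(sv[0], 1.0)
    rank = int(np.sum(sv > PLANE_TOL * scale))

    if rank == 0:
        return 1

    candidates = _bbox_lattice(pts)

    if rank == 3:
        hull = ConvexHull(pts)
        a, b = hull.equations[:, :3], hull.equations[:, 3]
        inside = np.all(candidates @ a.T + b <= HULL_TOL, axis=1)
        return int(inside.sum())

    # Degenerate: project onto the affine span and test membership there.
    _, _, vt = np.linalg.svd(centered, full_matrices=True)
    basis = vt[:rank]          # spans the object
    normal = vt[rank:]         # orthogonal complement
    p0 = pts[0]
    off = (candidates - p0) @ normal.T
    on_span = np.all(np.abs(off) <= PLANE_TOL * max(scale, 1.0), axis=1)
    cand = candidates[on_span]
    proj_pts = (pts - p0) @ basis.T
    proj_cand = (cand - p0) @ basis.T

    if rank == 1:
        t = proj_pts[:, 0]
        lo, hi = t.min() - HULL_TOL, t.max() + HULL_TOL
        return int(np.sum((proj_cand[:, 0] >= lo) & (proj_cand[:, 0] <= hi)))

    # rank == 2: planar hull
    try:
        hull = ConvexHull(proj_pts)
    except QhullError:
        # numerically collinear after projection; fall back to 1D span
        d = proj_pts - proj_pts.mean(axis=0)
        u = d[np.argmax(np.linalg.norm(d, axis=1))]
        u = u / np.linalg.norm(u)
        t = proj_pts @ u
        tc = proj_cand @ u
        return int(np.sum((tc >= t.min() - HULL_TOL) & (tc <= t.max() + HULL_TOL)))
    a, b = hull.equations[:, :2], hull.equations[:, 2]
    inside = np.all(proj_cand @ a.T + b <= HULL_TOL, axis=1)
    return int(inside.sum())


def solidity(
    cell_voxels: Iterable[tuple[int, int, int]] | np.ndarray,
    spacing: VoxelSpacing | None = None,
) -> float:
    """Voxel count divided by convex-hull lattice-point count, in (0, 1].

    Exactly 1 for any digitally convex object (filled cuboid, digital
    ball); strictly below 1 as soon as the object leaves lattice points of
    its hull unfilled, e.g. when ramified arms extend from a compact soma.
    """
    pts = _as_points(cell_voxels)
    return len(pts) / convex_voxel_count(pts, spacing)


def measure_cells(
    labels: LabelVolume,
    spacing: VoxelSpacing,
    lesion_id: str = "",
    eye_id: str = "",
) -> list[CellMorphology]:
    """One :class:`CellMorphology` record per label, in label order."""
    vol = labels.labels
    n = int(vol.max(initial=0))
    border = dict(flag_border_cells(labels))
    records: list[CellMorphology] = []
    objects = ndi.find_objects(vol)
    voxel_vol = spacing.voxel_volume_um3
    for lab in range(1, n + 1):
        sl = objects[lab - 1]
        if sl is None:
            continue
        local = np.argwhere(vol[sl] == lab)
        offset = np.array([s.start for s in sl])
        pts = local + offset
        count = len(pts)
        hull_count = convex_voxel_count(pts, spacing)
        records.append(
            CellMorphology(
                cell_id=lab,
                lesion_id=lesion_id,
                eye_id=eye_id,
                voxel_count=count,
                volume_um3=count * voxel_vol,
                convex_voxel_count=hull_count,
                solidity=count / hull_count,
                border_touching=border.get(lab, False),
            )
        )
    return records


def mean_solidity_per_eye(
    cells: Sequence[CellMorphology],
    exclude_border: bool = True,
    aggregate: str = "pooled",
) -> list[EyeSolidity]:
    """Mean cell solidity per eye.

    By default all cells of an eye are pooled across its lesion images
    before averaging; ``aggregate="by_lesion"`` instead averages the
    per-lesion means.  Border-touching cells are excluded by default:
    truncated arms inflate solidity.  Eyes with no eligible cells are
    omitted from the result rather than reported as NaN.
    """
    if aggregate not in ("pooled", "by_lesion"):
        raise ValueError(f"unknown aggregation mode {aggregate!r}")
    eligible = [c for c in cells if not (exclude_border and c.border_touching)]
    by_eye: dict[str, list[CellMorphology]] = {}
    for c in eligible:
        by_eye.setdefault(c.eye_id, []).append(c)
    out: list[EyeSolidity] = []
    for eye_id in sorted(by_eye):
        group = by_eye[eye_id]
        if aggregate == "pooled":
            mean = float(np.mean([c.solidity for c in group]))
        else:
            by_lesion: dict[str, list[float]] = {}
            for c in group:
                by_lesion.setdefault(c.lesion_id, []).append(c.solidity)
            mean = float(np.mean([np.mean(v) for v in by_lesion.values()]))
        out.append(EyeSolidity(eye_id=eye_id, n_cells=len(group), mean_solidity=mean))
    return out
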