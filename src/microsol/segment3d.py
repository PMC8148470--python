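"""Cell isolation in 3D: connected components, seeds, watershed split, filters.

The binarized volume is decomposed into objects under 26-connectivity
(diagonal adjacency included, to preserve the continuity of thin ramified
processes across anisotropic planes).  Objects too small or too large to be
an isolated cell or a small cell cluster are discarded; remaining clusters
are resolved by seeded watershed, using the bright soma centers as seeds;
finally residual non-cellular objects are removed by shape and size
filters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.segmentation import watershed

from .imaging_io import BinaryMask, ImageStack, VoxelSpacing

__all__ = [
    "LabelVolume",
    "SegmentationParams",
    "SeedSet",
    "detect_objects",
    "filter_by_size",
    "detect_bright_centers",
    "split_cells",
    "filter_by_shape",
    "flag_border_cells",
]

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class LabelVolume:
    """Integer-labeled 3D segmentation (0 = background, 1..N = objects)."""

    labels: np.ndarray
    spacing: VoxelSpacing

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if lab.ndim != 3:
            raise ValueError(f"labels must be 3D, got shape {lab.shape}")
        if not np.issubdtype(lab.dtype, np.integer):
            raise ValueError(f"labels must be integer, got dtype {lab.dtype}")
        self.labels = lab.astype(np.int32, copy=False)

    @property
    def n_labels(self) -> int:
        return int(self.labels.max(initial=0))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape


@dataclass(frozen=True)
class SegmentationParams:
    """Size, seed and shape parameters of the isolation chain.

    The first size gate (``min_object_voxels``/``max_object_voxels``) keeps
    anything that could be a cell *or a small cell cluster*; clusters are
    resolved downstream by multi-seed splitting, and the stricter per-cell
    gates (``min_cell_voxels``/``max_cell_voxels``) together with the
    elongation and extent cutoffs run after splitting.
    """

    min_object_voxels: int = 30
    max_object_voxels: int = 100_000
    seed_smooth_sigma_px: float = 2.0
    seed_min_distance_px: float = 8.0
    min_cell_voxels: int = 50
    max_cell_voxels: int = 20_000
    max_elongation: float = 12.0
    min_extent: float = 0.02

    def __post_init__(self) -> None:
        if not (0 < self.min_object_voxels < self.max_object_voxels):
            raise ValueError("need 0 < min_object_voxels < max_object_voxels")
        if not (0 < self.min_cell_voxels < self.max_cell_voxels):
            raise ValueError("need 0 < min_cell_voxels < max_cell_voxels")
        if self.seed_smooth_sigma_px <= 0:
            raise ValueError("seed_smooth_sigma_px must be > 0")
        if self.seed_min_distance_px < 1:
            raise ValueError("seed_min_distance_px must be >= 1")
        if self.max_elongation <= 1:
            raise ValueError("max_elongation must be > 1")
        if not (0 < self.min_extent < 1):
            raise ValueError("min_extent must lie in (0, 1)")


@dataclass
class SeedSet:
    """Bright-center seed coordinates (z, y, x) with their intensities."""

    points: list[tuple[int, int, int]]
    intensities: np.ndarray = field(default_factory=lambda: np.empty(0))


def detect_objects(mask: BinaryMask) -> LabelVolume:
    """Connected components under 26-connectivity.

    Labels are assigned in raster order of each component's first voxel,
    which makes the labeling deterministic.
    """
    labels, _ = ndi.label(mask.voxels, structure=_STRUCT_26)
    return LabelVolume(labels=labels, spacing=mask.spacing)


def _relabel_keep(labels: np.ndarray, keep: np.ndarray) -> np.ndarray:
    """Relabel so surviving labels form 1..N preserving their order."""
    n = int(labels.max(initial=0))
    mapping = np.zeros(n + 1, dtype=labels.dtype)
    mapping[keep] = np.arange(1, len(keep) + 1)
    return mapping[labels]


def filter_by_size(labels: LabelVolume, params: SegmentationParams) -> LabelVolume:
    """Drop objects outside [min_object_voxels, max_object_voxels]."""
    n = labels.n_labels
    if n == 0:
        return LabelVolume(labels=labels.labels.copy(), spacing=labels.spacing)
    counts = np.bincount(labels.labels.ravel(), minlength=n + 1)
    keep = np.flatnonzero(
        (counts >= params.min_object_voxels) & (counts <= params.max_object_voxels)
    )
    keep = keep[keep > 0]
    return LabelVolume(labels=_relabel_keep(labels.labels, keep), spacing=labels.spacing)


def _smooth_xy(voxels: np.ndarray, sigma: float) -> np.ndarray:
    # smoothing in-plane only: the 2.5 um axial step is far coarser than the
    # lateral pixel size, and isotropic 3D smoothing over-merges somata
    # across planes
    return ndi.gaussian_filter(voxels.astype(np.float64), sigma=(0.0, sigma, sigma))


def detect_bright_centers(
    stack: ImageStack, labels: LabelVolume, params: SegmentationParams
) -> SeedSet:
    """Find one-or-more soma seeds per object from intensity local maxima.

    Local maxima of the xy-smoothed intensity restricted to labeled voxels
    are thinned greedily so no two seeds lie within ``seed_min_distance_px``
    of each other in the xy plane; on conflict the brighter seed wins, with
    raster order breaking exact intensity ties.  Any object whose seeds were
    all removed gets its global (smoothed) intensity maximum back, so every
    object keeps at least one seed.
    """
    if stack.shape != labels.shape:
        raise ValueError("stack and labels must share geometry")
    smoothed = _smooth_xy(stack.voxels, params.seed_smooth_sigma_px)
    lab = labels.labels
    fg = lab > 0
    local_max = (smoothed == ndi.maximum_filter(smoothed, footprint=_STRUCT_26, mode="nearest")) & fg
    # a flat plateau (e.g. a uniform-intensity object) is one maximum, not
    # many: collapse each connected plateau to its first voxel in raster order
    plateaus, n_plateaus = ndi.label(local_max, structure=_STRUCT_26)
    if n_plateaus:
        flat_first = np.full(n_plateaus + 1, -1, dtype=np.int64)
        flat = plateaus.ravel()
        idx = np.flatnonzero(flat)
        # reversed so the smallest raster index wins
        flat_first[flat[idx[::-1]]] = idx[::-1]
        local_max = np.zeros_like(local_max)
        local_max.ravel()[flat_first[1:]] = True
    cand = np.argwhere(local_max)
    if cand.size:
        inten = smoothed[tuple(cand.T)]
        order = np.lexsort((cand[:, 2], cand[:, 1], cand[:, 0], -inten))
        cand = cand[order]
        inten = inten[order]
    else:
        inten = np.empty(0)

    accepted: list[np.ndarray] = []
    accepted_int: list[float] = []
    d2 = params.seed_min_distance_px**2
    for p, v in zip(cand, inten):
        ok = True
        for q in accepted:
            dy, dx = p[1] - q[1], p[2] - q[2]
            if dy * dy + dx * dx < d2:
                ok = False
                break
        if ok:
            accepted.append(p)
            accepted_int.append(float(v))

    seeded = {int(lab[tuple(p)]) for p in accepted}
    for obj in range(1, labels.n_labels + 1):
        if obj in seeded:
            continue
        idx = np.argwhere(lab == obj)
        vals = smoothed[tuple(idx.T)]
        p = idx[int(np.argmax(vals))]  # argmax is raster-first on ties
        accepted.append(p)
        accepted_int.append(float(vals.max()))

    # deterministic output order: raster order of the seed coordinates
    pts = [tuple(int(c) for c in p) for p in accepted]
    order = np.lexsort(tuple(np.array([p[i] for p in pts]) for i in (2, 1, 0))) if pts else []
    points = [pts[i] for i in order]
    intensities = np.array([accepted_int[i] for i in order])
    return SeedSet(points=points, intensities=intensities)


def split_cells(
    labels: LabelVolume,
    seeds: SeedSet,
    stack: ImageStack,
    params: SegmentationParams | None = None,
) -> LabelVolume:
    """Partition each multi-seed object by seeded watershed.

    Flooding runs on the negated xy-smoothed intensity, constrained to the
    parent object, so each seed claims the basin around its soma.
    Single-seed objects pass through unchanged.  The output label count
    equals the seed count, and splitting conserves the labeled voxel set.
    """
    params = params or SegmentationParams()
    lab = labels.labels
    for p in seeds.points:
        if lab[p] == 0:
            raise ValueError(f"seed {p} lies outside the foreground")
    smoothed = _smooth_xy(stack.voxels, params.seed_smooth_sigma_px)

    by_object: dict[int, list[tuple[int, int, int]]] = {}
    for p in seeds.points:
        by_object.setdefault(int(lab[p]), []).append(p)

    out = np.zeros_like(lab)
    next_label = 1
    objects = ndi.find_objects(lab)
    for obj in range(1, labels.n_labels + 1):
        sl = objects[obj - 1]
        if sl is None:
            continue
        pts = by_object.get(obj, [])
        region = lab[sl] == obj
        if len(pts) <= 1:
            out[sl][region] = next_label
            next_label += 1
            continue
        markers = np.zeros(region.shape, dtype=np.int32)
        offset = np.array([s.start for s in sl])
        for i, p in enumerate(pts, start=1):
            markers[tuple(np.array(p) - offset)] = i
        ws = watershed(-smoothed[sl], markers=markers, mask=region)
        out[sl][region] = ws[region] + (next_label - 1)
        next_label += len(pts)
    return LabelVolume(labels=out, spacing=labels.spacing)


def _shape_stats(pts: np.ndarray, spacing: VoxelSpacing) -> tuple[float, float]:
    """(elongation, extent) of one object's voxel coordinates.

    Elongation is the largest/smallest eigenvalue ratio of the physical
    voxel-coordinate covariance.  The covariance is regularized by the
    second moment of a single voxel (edge^2/12 per axis) so that flat or
    single-voxel objects have a finite, scale-appropriate ratio.
    """
    phys = pts * np.array(spacing.as_zyx())
    cov = np.cov(phys.T) if len(pts) > 1 else np.zeros((3, 3))
    cov = cov + np.diag(np.array(spacing.as_zyx()) ** 2) / 12.0
    ev = np.linalg.eigvalsh(cov)
    elong = float(ev[-1] / ev[0])
    span = pts.max(axis=0) - pts.min(axis=0) + 1
    extent = float(len(pts) / np.prod(span))
    return elong, extent


def filter_by_shape(labels: LabelVolume, params: SegmentationParams) -> LabelVolume:
    """Remove non-cellular objects by per-cell size, elongation and extent.

    A cell survives iff its voxel count lies in
    [min_cell_voxels, max_cell_voxels], its principal-axis elongation is
    <= max_elongation and its bounding-box extent is >= min_extent.
    """
    lab = labels.labels
    keep: list[int] = []
    objects = ndi.find_objects(lab)
    for obj in range(1, labels.n_labels + 1):
        sl = objects[obj - 1]
        if sl is None:
            continue
        local = np.argwhere(lab[sl] == obj)
        count = len(local)
        if count < params.min_cell_voxels or count > params.max_cell_voxels:
            continue
        elong, extent = _shape_stats(local, labels.spacing)
        if elong > params.max_elongation or extent < params.min_extent:
            continue
        keep.append(obj)
    return LabelVolume(labels=_relabel_keep(lab, np.array(keep, dtype=int)), spacing=labels.spacing)


def write_label_tiff(labels: LabelVolume, path) -> None:
    """Dump a label volume as a 16-bit multi-page TIFF for visual inspection."""
    import tifffile

    if labels.n_labels > 65535:
        raise ValueError("more than 65535 labels cannot be stored as uint16")
    tifffile.imwrite(path, labels.labels.astype(np.uint16), photometric="minisblack")


def flag_border_cells(labels: LabelVolume) -> list[tuple[int, bool]]:
    """True iff any voxel of the cell lies on the first/last plane of any axis."""
    lab = labels.labels
    n = labels.n_labels
    if n == 0:
        return []
    border = np.zeros(lab.shape, dtype=bool)
    for axis in range(3):
        sl: list = [slice(None)] * 3
        sl[axis] = 0
        border[tuple(sl)] = True
        sl[axis] = -1
        border[tuple(sl)] = True
    touching = np.unique(lab[border])
    touching = set(int(t) for t in touching if t > 0)
    return [(obj, obj in touching) for obj in range(1, n + 1)]
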