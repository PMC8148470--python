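"""Synthetic Iba1-like microglia stacks with voxel-level ground truth.

The generator emulates the statistical structure the quantification chain
assumes — a bright ellipsoidal soma, dimmer thin ramified arms, a smooth
additive background gradient and Gaussian sensor noise on an anisotropic
voxel grid — without attempting photorealism (no point-spread function, no
spectral crosstalk).  Resting (ramified) cells carry several long wavy
arms; activated (amoeboid) cells are nearly bare somata.  Every scene is a
pure function of its parameters and a single integer seed: per-cell random
streams are derived from the scene seed by a fixed spawning rule, so any
sub-object can be regenerated in isolation.

Rasterization uses physical distances, so the 2.5 um axial step naturally
under-samples arms relative to the lateral pixel grid, as in real confocal
stacks of flat-mounted tissue.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import morphometry
from .imaging_io import ImageStack, VoxelSpacing, write_stack

__all__ = [
    "CellPhenotypeParams",
    "PhenotypeDistribution",
    "SceneParams",
    "TrueCell",
    "SyntheticGroundTruth",
    "RAMIFIED",
    "AMOEBOID",
    "generate_cell_mask",
    "generate_scene",
    "generate_flatmount",
    "generate_cohort",
]


@dataclass(frozen=True)
class CellPhenotypeParams:
    """Morphological model of one cell.

    Units are micrometres and arbitrary intensity units.  ``branch_tortuosity``
    in [0, 1] scales the per-step angular jitter of the random-walk arms
    (0 = straight rays, 1 = strongly wavy).
    """

    soma_radius_um: float = 5.5
    n_branches: int = 6
    branch_length_um: float = 15.0
    branch_width_um: float = 6.0
    branch_tortuosity: float = 0.35
    soma_peak_intensity: float = 200.0
    branch_intensity: float = 130.0

    def __post_init__(self) -> None:
        if self.soma_radius_um <= 0 or self.branch_length_um <= 0 or self.branch_width_um <= 0:
            raise ValueError("radii and lengths must be > 0")
        if self.n_branches < 0:
            raise ValueError("n_branches must be >= 0")
        if not (0 <= self.branch_tortuosity <= 1):
            raise ValueError("branch_tortuosity must lie in [0, 1]")
        if self.branch_intensity > self.soma_peak_intensity:
            raise ValueError("branch intensity must not exceed soma intensity")


# Default structures are sized to span at least two 2.5-um axial planes
# (soma diameter >= 11 um, arm width 6 um): thinner processes fall below
# the axial sampling limit of the modeled acquisition and vanish in the
# denoising step, which would make ground truth unrecoverable by any
# method operating on the sampled volume.
RAMIFIED = CellPhenotypeParams()
AMOEBOID = CellPhenotypeParams(
    soma_radius_um=6.5, n_branches=1, branch_length_um=5.0, branch_width_um=6.0,
    branch_tortuosity=0.2,
)


@dataclass(frozen=True)
class PhenotypeDistribution:
    """Per-cell jitter around a base phenotype, sampled once per cell."""

    base: CellPhenotypeParams
    n_branches_jitter: int = 1
    length_jitter_frac: float = 0.2
    soma_jitter_frac: float = 0.1

    def sample(self, rng: np.random.Generator) -> CellPhenotypeParams:
        n = max(0, self.base.n_branches + int(rng.integers(-self.n_branches_jitter, self.n_branches_jitter + 1)))
        return replace(
            self.base,
            n_branches=n,
            branch_length_um=self.base.branch_length_um * float(rng.uniform(1 - self.length_jitter_frac, 1 + self.length_jitter_frac)),
            soma_radius_um=self.base.soma_radius_um * float(rng.uniform(1 - self.soma_jitter_frac, 1 + self.soma_jitter_frac)),
        )


@dataclass(frozen=True)
class SceneParams:
    """Acquisition geometry and nuisance structure of one synthetic stack.

    Defaults model the study geometry: a 780 um square field sampled at
    512 px per side (dx = dy = 780/512 um) with 2.5 um z-steps over a
    30 um deep stack.  ``background`` is (offset, ramp amplitude across x);
    noise is additive Gaussian, clipped at zero.
    """

    field_size_um: float = 780.0
    depth_um: float = 30.0
    dx: float = 780.0 / 512
    dy: float = 780.0 / 512
    dz: float = 2.5
    n_cells: int = 8
    min_centroid_separation_um: float = 90.0
    background_offset: float = 20.0
    background_ramp: float = 15.0
    noise_sd: float = 8.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if min(self.field_size_um, self.depth_um, self.dx, self.dy, self.dz) <= 0:
            raise ValueError("geometry parameters must be > 0")

    @property
    def spacing(self) -> VoxelSpacing:
        return VoxelSpacing(dx=self.dx, dy=self.dy, dz=self.dz)

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        nz = max(1, round(self.depth_um / self.dz))
        ny = max(1, round(self.field_size_um / self.dy))
        nx = max(1, round(self.field_size_um / self.dx))
        return (nz, ny, nx)


@dataclass
class TrueCell:
    """Ground truth for one generated cell."""

    index: int
    phenotype: str
    params: CellPhenotypeParams
    center_zyx: tuple[int, int, int]
    voxels: np.ndarray          # (n, 3) int lattice coordinates, pairwise disjoint across cells
    true_solidity: float
    true_voxel_count: int


@dataclass
class SyntheticGroundTruth:
    cells: list[TrueCell]
    seed: int


def _cell_rng(seed: int, index: int) -> np.random.Generator:
    # fixed splitting rule: scene seed + cell index spawn an independent stream
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(int(index),)))


def _stamp_ball(center_um: np.ndarray, radius_um: float, spacing: VoxelSpacing) -> set[tuple[int, int, int]]:
    """Lattice points within physical ``radius_um`` of a physical point."""
    d = np.array(spacing.as_zyx())
    lo = np.floor((center_um - radius_um) / d).astype(int)
    hi = np.ceil((center_um + radius_um) / d).astype(int)
    zz, yy, xx = np.meshgrid(*(np.arange(a, b + 1) for a, b in zip(lo, hi)), indexing="ij")
    pts = np.stack([zz.ravel(), yy.ravel(), xx.ravel()], axis=1)
    dist2 = ((pts * d - center_um) ** 2).sum(axis=1)
    return {tuple(p) for p in pts[dist2 <= radius_um**2]}


def generate_cell_mask(
    phenotype: CellPhenotypeParams,
    spacing: VoxelSpacing,
    rng: np.random.Generator,
) -> tuple[set[tuple[int, int, int]], set[tuple[int, int, int]]]:
    """Rasterize one cell centered at lattice origin.

    Returns ``(soma_voxels, branch_voxels)`` as sets of (z, y, x) integer
    coordinates (branch voxels exclude the soma).  The soma is the digital
    ball of physical radius ``soma_radius_um``; each arm is a random-walk
    tube of the given width and length starting on the soma surface, with
    per-step angular jitter set by the tortuosity.  Arm directions are
    biased toward the imaging plane, as processes of cells in flat-mounted
    tissue spread laterally.  The union is 26-connected by construction
    (steps are shorter than the tube radius).
    """
    origin = np.zeros(3)
    soma = _stamp_ball(origin, phenotype.soma_radius_um, spacing)
    if not soma:
        raise ValueError("parameters yield an empty soma mask")
    branches: set[tuple[int, int, int]] = set()
    step = min(1.0, phenotype.branch_width_um / 2)
    n_steps = max(1, round(phenotype.branch_length_um / step))
    jitter_sd = 0.5 * phenotype.branch_tortuosity
    for _ in range(phenotype.n_branches):
        # initial direction: uniform azimuth, flattened polar component
        phi = rng.uniform(0, 2 * math.pi)
        zc = rng.normal(0.0, 0.25)
        d = np.array([zc, math.sin(phi), math.cos(phi)])
        d /= np.linalg.norm(d)
        pos = d * phenotype.soma_radius_um
        for _ in range(n_steps):
            branches |= _stamp_ball(pos, phenotype.branch_width_um / 2, spacing)
            # jitter the direction, then renormalize; z-jitter damped
            d = d + rng.normal(0.0, jitter_sd, size=3) * np.array([0.3, 1.0, 1.0])
            d /= np.linalg.norm(d)
            pos = pos + d * step
    return soma, branches - soma


def generate_scene(
    scene: SceneParams,
    phenotypes: Sequence[CellPhenotypeParams] | None = None,
    phenotype_names: Sequence[str] | None = None,
) -> tuple[ImageStack, SyntheticGroundTruth]:
    """Render a full stack of cells over background gradient and noise.

    Cell centroids are placed by rejection sampling at pairwise xy distance
    >= ``min_centroid_separation_um`` (bounded retries; failure raises).
    Voxel intensity is soma/branch value + linear background ramp along x +
    Gaussian noise, clipped at 0.  Where two cells would overlap, the voxel
    stays with the earlier cell so true masks remain pairwise disjoint.
    """
    if phenotypes is None:
        phenotypes = [RAMIFIED] * scene.n_cells
    if len(phenotypes) != scene.n_cells:
        raise ValueError("need one phenotype per cell")
    if phenotype_names is None:
        phenotype_names = ["ramified" if p.n_branches >= 3 else "amoeboid" for p in phenotypes]
    spacing = scene.spacing
    nz, ny, nx = scene.grid_shape
    place_rng = _cell_rng(scene.rng_seed, 10_000)
    margin_um = max(p.soma_radius_um + p.branch_length_um for p in phenotypes) + 2.0
    lo_y = lo_x = margin_um
    hi_y = scene.field_size_um - margin_um
    hi_x = scene.field_size_um - margin_um
    if hi_y <= lo_y or hi_x <= lo_x:
        raise ValueError("field too small for the requested cell size")

    centers_um: list[np.ndarray] = []
    for _attempt in range(200 * scene.n_cells):
        if len(centers_um) == scene.n_cells:
            break
        y = place_rng.uniform(lo_y, hi_y)
        x = place_rng.uniform(lo_x, hi_x)
        z = scene.depth_um / 2 + place_rng.uniform(-0.15, 0.15) * scene.depth_um
        c = np.array([z, y, x])
        if all(math.hypot(c[1] - q[1], c[2] - q[2]) >= scene.min_centroid_separation_um for q in centers_um):
            centers_um.append(c)
    if len(centers_um) != scene.n_cells:
        raise ValueError(
            f"could not place {scene.n_cells} cells at separation "
            f"{scene.min_centroid_separation_um} um in a {scene.field_size_um} um field"
        )

    image = np.empty((nz, ny, nx), dtype=np.float64)
    image[:] = scene.background_offset + scene.background_ramp * (np.arange(nx) / max(nx - 1, 1))

    occupied = np.zeros((nz, ny, nx), dtype=bool)
    truth_cells: list[TrueCell] = []
    d = np.array(spacing.as_zyx())
    for i, (pheno, name) in enumerate(zip(phenotypes, phenotype_names)):
        rng = _cell_rng(scene.rng_seed, i)
        soma, branch = generate_cell_mask(pheno, spacing, rng)
        center_vox = np.rint(centers_um[i] / d).astype(int)

        def _shift_clip(vox: set[tuple[int, int, int]]) -> np.ndarray:
            if not vox:
                return np.empty((0, 3), dtype=int)
            arr = np.array(sorted(vox)) + center_vox
            ok = np.all((arr >= 0) & (arr < [nz, ny, nx]), axis=1)
            return arr[ok]

        soma_abs = _shift_clip(soma)
        branch_abs = _shift_clip(branch)
        cell_vox = []
        for arr, inten in ((branch_abs, pheno.branch_intensity), (soma_abs, pheno.soma_peak_intensity)):
            if len(arr) == 0:
                continue
            idx = tuple(arr.T)
            free = ~occupied[idx]
            arr = arr[free]
            if len(arr) == 0:
                continue
            idx = tuple(arr.T)
            image[idx] += inten
            occupied[idx] = True
            cell_vox.append(arr)
        pts = np.concatenate(cell_vox) if cell_vox else np.empty((0, 3), dtype=int)
        if len(pts) == 0:
            raise ValueError(f"cell {i} fell entirely outside the volume")
        truth_cells.append(
            TrueCell(
                index=i,
                phenotype=name,
                params=pheno,
                center_zyx=tuple(int(v) for v in center_vox),
                voxels=pts,
                true_solidity=morphometry.solidity(pts),
                true_voxel_count=len(pts),
            )
        )

    if scene.noise_sd > 0:
        noise_rng = _cell_rng(scene.rng_seed, 20_000)
        image += noise_rng.normal(0.0, scene.noise_sd, size=image.shape)
    np.maximum(image, 0.0, out=image)
    stack = ImageStack(voxels=image.astype(np.float32), spacing=spacing, name=f"scene-{scene.rng_seed}")
    return stack, SyntheticGroundTruth(cells=truth_cells, seed=scene.rng_seed)


def generate_flatmount(
    scene: SceneParams,
    lesion_fraction: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, float]:
    """2D flat-mount-like image with a bright disk lesion of known area.

    Returns ``(image, true_fraction)`` where ``true_fraction`` is the exact
    rasterized stained-pixel fraction (close to, but not exactly, the
    requested ``lesion_fraction``).  Background is a dim gradient plus
    Gaussian texture; the lesion is a bright filled disk at a jittered
    center.
    """
    if not (0 <= lesion_fraction <= 1):
        raise ValueError("lesion_fraction must lie in [0, 1]")
    side = max(1, round(scene.field_size_um / scene.dx))
    yy, xx = np.mgrid[0:side, 0:side]
    image = scene.background_offset + scene.background_ramp * (xx / max(side - 1, 1))
    if lesion_fraction > 0:
        radius = math.sqrt(lesion_fraction * side * side / math.pi)
        cy = side / 2 + rng.uniform(-0.05, 0.05) * side
        cx = side / 2 + rng.uniform(-0.05, 0.05) * side
        stained = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2
    else:
        stained = np.zeros((side, side), dtype=bool)
    image = image + stained * 180.0
    if scene.noise_sd > 0:
        image = image + rng.normal(0.0, scene.noise_sd, size=image.shape)
    image = np.maximum(image, 0.0)
    return image.astype(np.float32), float(stained.mean())


def generate_cohort(
    n_eyes_per_group: int,
    group_phenotypes: Mapping[str, PhenotypeDistribution],
    scene: SceneParams,
    out_dir: str | Path,
    lesions_per_eye: int = 4,
    keep_masks: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, SyntheticGroundTruth]]:
    """Write a reproducible multi-arm cohort of stacks to disk.

    One stack per (eye, lesion); per-stack seeds are derived from
    ``scene.rng_seed`` by a fixed rule, so the cohort is bit-reproducible.
    Returns ``(manifest, ground_truth, truths)`` where ``manifest`` has one
    row per stack (image_id, eye_id, lesion_id, group, path), ``ground_truth``
    one row per generated cell (true centroid, phenotype, solidity), and
    ``truths`` maps image_id to the full in-memory ground truth (with voxel
    masks only when ``keep_masks`` is set).  Both frames are also written as
    ``manifest.csv`` / ``ground_truth.csv`` in ``out_dir``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest_rows = []
    truth_rows = []
    truths: dict[str, SyntheticGroundTruth] = {}
    stack_idx = 0
    for g, group in enumerate(sorted(group_phenotypes)):
        dist = group_phenotypes[group]
        for eye in range(n_eyes_per_group):
            eye_id = f"{group}-eye{eye + 1}"
            for lesion in range(lesions_per_eye):
                stack_seed = scene.rng_seed * 1_000_003 + stack_idx
                stack_idx += 1
                pheno_rng = _cell_rng(stack_seed, 30_000)
                phenos = [dist.sample(pheno_rng) for _ in range(scene.n_cells)]
                names = [f"{group}" for _ in phenos]
                sp = replace(scene, rng_seed=stack_seed)
                stack, truth = generate_scene(sp, phenos, names)
                image_id = f"{eye_id}-lesion{lesion + 1}"
                path = out_dir / f"{image_id}.tif"
                stack.name = image_id
                write_stack(stack, path)
                manifest_rows.append(
                    {"image_id": image_id, "eye_id": eye_id, "lesion_id": f"lesion{lesion + 1}",
                     "group": group, "path": str(path)}
                )
                for cell in truth.cells:
                    truth_rows.append(
                        {"image_id": image_id, "eye_id": eye_id, "group": group,
                         "cell_index": cell.index,
                         "center_z": cell.center_zyx[0], "center_y": cell.center_zyx[1],
                         "center_x": cell.center_zyx[2],
                         "phenotype": cell.phenotype,
                         "true_voxel_count": cell.true_voxel_count,
                         "true_solidity": cell.true_solidity}
                    )
                if not keep_masks:
                    for cell in truth.cells:
                        cell.voxels = np.empty((0, 3), dtype=int)
                truths[image_id] = truth
    manifest = pd.DataFrame(manifest_rows)
    ground_truth = pd.DataFrame(truth_rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    ground_truth.to_csv(out_dir / "ground_truth.csv", index=False, float_format="%.9g")
    return manifest, ground_truth, truths
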