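"""Independent brute-force oracles used to freeze expected values.

Each oracle recomputes a quantity from its definition by exhaustive
scanning/enumeration, deliberately avoiding the code paths of the package
implementation it checks.
"""

from __future__ import annotations

import itertools
import math
from typing import Sequence

import numpy as np
from scipy.spatial import Delaunay


def opening_oracle(plane: np.ndarray, footprint: np.ndarray) -> np.ndarray:
    """Grayscale opening by explicit min-then-max window scans.

    Edge handling replicates edge-value padding by clamping indices.
    """
    offsets = np.argwhere(footprint) - np.array(footprint.shape) // 2
    h, w = plane.shape

    def scan(img, reduce_fn):
        out = np.empty_like(img)
        for i in range(h):
            for j in range(w):
                vals = []
                for di, dj in offsets:
                    ii = min(max(i + di, 0), h - 1)
                    jj = min(max(j + dj, 0), w - 1)
                    vals.append(img[ii, jj])
                out[i, j] = reduce_fn(vals)
        return out

    return scan(scan(plane, min), max)


def otsu_oracle(values: np.ndarray, bins: int) -> float:
    """Exhaustive scan of all histogram splits for max between-class variance."""
    values = np.asarray(values, dtype=float).ravel()
    counts, edges = np.histogram(values, bins=bins, range=(values.min(), values.max()))
    centers = 0.5 * (edges[:-1] + edges[1:])
    variances = []
    for k in range(bins - 1):
        w0 = counts[: k + 1].sum()
        w1 = counts[k + 1 :].sum()
        if w0 == 0 or w1 == 0:
            variances.append(0.0)
        else:
            mu0 = (counts[: k + 1] * centers[: k + 1]).sum() / w0
            mu1 = (counts[k + 1 :] * centers[k + 1 :]).sum() / w1
            variances.append(float(w0) * float(w1) * (mu0 - mu1) ** 2)
    best = max(variances)
    # exact plateaus occur when modes are separated by empty bins; pick the
    # first maximizer at float precision, as the implementation contract does
    for k, v in enumerate(variances):
        if v >= best * (1 - 1e-10):
            return float(edges[k + 1])
    raise AssertionError("unreachable")


def majority_oracle(mask: np.ndarray, r: int) -> np.ndarray:
    """Per-voxel strict-majority vote over the clipped (2r+1)^3 cube."""
    nz, ny, nx = mask.shape
    out = np.zeros_like(mask)
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                block = mask[
                    max(z - r, 0) : z + r + 1,
                    max(y - r, 0) : y + r + 1,
                    max(x - r, 0) : x + r + 1,
                ]
                out[z, y, x] = block.sum() * 2 > block.size
    return out


def hull_count_oracle(points: np.ndarray) -> int:
    """Lattice points inside the convex hull, by Delaunay point location.

    Uses Qhull's triangulation + point location (a different code path than
    facet half-space testing).  Degenerate inputs are lifted by appending an
    epsilon-perturbed copy so the triangulation exists; the perturbation is
    small enough not to change lattice membership.
    """
    pts = np.asarray(points, dtype=float)
    lo = np.floor(pts.min(axis=0)).astype(int)
    hi = np.ceil(pts.max(axis=0)).astype(int)
    cand = np.array(list(itertools.product(*(range(a, b + 1) for a, b in zip(lo, hi)))), dtype=float)
    try:
        tri = Delaunay(pts)
    except Exception:
        # degenerate (flat) set: thicken symmetrically by +-eps along every axis
        eps = 1e-6
        shifted = np.concatenate([pts + e for e in itertools.product([-eps, eps], repeat=3)])
        tri = Delaunay(shifted)
    inside = tri.find_simplex(cand, tol=1e-9) >= 0
    return int(inside.sum())


def ball_count_oracle(radius_um: float, spacing_zyx: tuple[float, float, float]) -> int:
    """Lattice points within a physical radius of the origin, by direct test."""
    dz, dy, dx = spacing_zyx
    rz, ry, rx = (int(math.ceil(radius_um / d)) for d in (dz, dy, dx))
    count = 0
    for z in range(-rz, rz + 1):
        for y in range(-ry, ry + 1):
            for x in range(-rx, rx + 1):
                if (z * dz) ** 2 + (y * dy) ** 2 + (x * dx) ** 2 <= radius_um**2:
                    count += 1
    return count


def mann_whitney_exact_oracle(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney by full enumeration of group assignments.

    Returns (U of group a, two-sided p).  Assumes no ties.
    """
    a = list(a)
    b = list(b)
    pooled = a + b
    n, na = len(pooled), len(a)

    def u_of(group_a):
        rest = list(pooled)
        for v in group_a:
            rest.remove(v)
        return sum(1 for x in group_a for y in rest if x > y)

    u_obs = u_of(a)
    dist = [u_of(list(c)) for c in itertools.combinations(pooled, na)]
    dist = np.array(dist)
    p_low = np.mean(dist <= u_obs)
    p_high = np.mean(dist >= u_obs)
    return float(u_obs), float(min(1.0, 2 * min(p_low, p_high)))


def kruskal_h_oracle(groups: Sequence[Sequence[float]]) -> float:
    """Kruskal-Wallis H from explicit rank arithmetic (no ties)."""
    pooled = sorted(v for g in groups for v in g)
    rank = {v: i + 1 for i, v in enumerate(pooled)}
    n = len(pooled)
    h = 0.0
    for g in groups:
        r = sum(rank[v] for v in g)
        h += r * r / len(g)
    return 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
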