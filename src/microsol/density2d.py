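"""Stained-area density on 2D projections and the OCT lesion-thickness ratio.

For each lesion image the fraction of pixels occupied by the staining is
measured on a maximum-intensity projection, averaged per eye, and expressed
as a percentage of the control-group mean.  Lesion swelling measured by
optical coherence tomography is summarized as (b - c)/c, with b the lesion
thickness and c the adjacent choroid thickness.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .imaging_io import ImageStack
from .preprocess import otsu_threshold_values

__all__ = [
    "DensityResult",
    "OctMeasurement",
    "max_intensity_projection",
    "stained_area_fraction",
    "pooled_otsu_threshold",
    "normalize_to_control",
    "oct_ratio",
]


@dataclass
class DensityResult:
    """Per-image stained-area fraction with optional eye-level aggregates."""

    image_id: str
    eye_id: str
    area_fraction: float
    eye_mean_fraction: float | None = None
    normalized_percent: float | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.area_fraction <= 1):
            raise ValueError("area_fraction must lie in [0, 1]")
        if self.normalized_percent is not None and self.normalized_percent < 0:
            raise ValueError("normalized_percent must be >= 0")


@dataclass(frozen=True)
class OctMeasurement:
    """One OCT reading: lesion thickness b, adjacent choroid thickness c (um)."""

    b: float
    c: float

    def __post_init__(self) -> None:
        if self.c <= 0:
            raise ValueError("adjacent choroid thickness c must be > 0")

    @property
    def ratio(self) -> float:
        return (self.b - self.c) / self.c


def max_intensity_projection(stack: ImageStack) -> np.ndarray:
    """Per-(y, x) maximum over z."""
    return stack.voxels.max(axis=0)


def stained_area_fraction(
    image: np.ndarray,
    threshold: float | str = "otsu",
    otsu_bins: int = 256,
) -> tuple[float, float]:
    """Fraction of pixels strictly above the threshold.

    ``threshold`` may be a fixed intensity or ``"otsu"`` to derive it from
    the image's own histogram.  Returns ``(fraction, threshold_used)``.
    For group comparisons prefer one pooled threshold per staining channel
    (see :func:`pooled_otsu_threshold`): per-image thresholds confound the
    density contrast between arms.
    """
    image = np.asarray(image)
    if isinstance(threshold, str):
        if threshold != "otsu":
            raise ValueError(f"unknown threshold policy {threshold!r}")
        t = otsu_threshold_values(image, otsu_bins)
    else:
        t = float(threshold)
    return float((image > t).mean()), t


def pooled_otsu_threshold(images: Sequence[np.ndarray], otsu_bins: int = 256) -> float:
    """One Otsu threshold from the pooled histogram of an experiment arm."""
    if not images:
        raise ValueError("need at least one image")
    pooled = np.concatenate([np.asarray(im).ravel() for im in images])
    return otsu_threshold_values(pooled, otsu_bins)


def normalize_to_control(
    eye_means: Mapping[str, float],
    control_eye_means: Mapping[str, float],
) -> dict[str, float]:
    """Express each eye's mean fraction as a percent of the control mean.

    The denominator is the grand mean of the control eyes' per-eye mean
    fractions; the control arm normalized against itself therefore averages
    100.  Scale-equivariant: rescaling all fractions by a common factor
    leaves the output unchanged.
    """
    if not control_eye_means:
        raise ValueError("control group is empty")
    control_mean = float(np.mean(list(control_eye_means.values())))
    if control_mean == 0:
        raise ValueError("control group mean is zero; cannot normalize")
    return {eye: 100.0 * v / control_mean for eye, v in eye_means.items()}


def oct_ratio(b: float, c: float) -> float:
    """(b - c)/c: lesion thickness relative to the adjacent choroid."""
    return OctMeasurement(b=b, c=c).ratio


def oct_ratios_from_csv(path) -> pd.DataFrame:
    """Read a 3-column CSV (id, b, c) and append the (b - c)/c ratio."""
    df = pd.read_csv(path)
    if df.shape[1] < 3:
        raise ValueError("OCT CSV must have at least 3 columns: id, b, c")
    id_col, b_col, c_col = df.columns[:3]
    df = df.rename(columns={id_col: "id", b_col: "b", c_col: "c"})
    df["ratio"] = [oct_ratio(b, c) for b, c in zip(df["b"], df["c"])]
    return df
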