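"""End-to-end quantification of one stack: preprocess, segment, measure."""

from __future__ import annotations

from dataclasses import dataclass

from . import morphometry, preprocess, segment3d
from .imaging_io import BinaryMask, ImageStack
from .preprocess import PreprocessParams
from .segment3d import LabelVolume, SeedSet, SegmentationParams

__all__ = ["StackResult", "quantify_stack"]


@dataclass
class StackResult:
    """All intermediates of one stack's quantification."""

    stack: ImageStack
    background_subtracted: ImageStack
    threshold: float
    mask: BinaryMask
    labels: LabelVolume
    seeds: SeedSet
    cells: list[morphometry.CellMorphology]


def quantify_stack(
    stack: ImageStack,
    pre: PreprocessParams | None = None,
    seg: SegmentationParams | None = None,
    lesion_id: str = "",
    eye_id: str = "",
) -> StackResult:
    """Run the full chain on one stack.

    Background opening and subtraction, global Otsu binarization, majority
    denoising, 26-connected components, the coarse size gate, bright-center
    seeding, watershed splitting of multi-seed clusters, shape/size
    filtering, and per-cell solidity measurement.
    """
    pre = pre or PreprocessParams()
    seg = seg or SegmentationParams()
    background = preprocess.estimate_background(stack, pre)
    sub = preprocess.subtract_background(stack, background)
    threshold, mask = preprocess.otsu_threshold(sub, pre)
    mask = preprocess.median_denoise(mask, pre)
    labels = segment3d.detect_objects(mask)
    labels = segment3d.filter_by_size(labels, seg)
    seeds = segment3d.detect_bright_centers(sub, labels, seg)
    labels = segment3d.split_cells(labels, seeds, sub, seg)
    labels = segment3d.filter_by_shape(labels, seg)
    cells = morphometry.measure_cells(labels, stack.spacing, lesion_id=lesion_id, eye_id=eye_id)
    return StackResult(
        stack=stack,
        background_subtracted=sub,
        threshold=threshold,
        mask=mask,
        labels=labels,
        seeds=seeds,
        cells=cells,
    )
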