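"""Nuclear-shape oscillation statistic.

The four-step procedure on the chromatin channel: (1) binarize the 2D nuclear
projection, (2) take the binary area A_T per time point, (3) form the
symmetric difference XOR(A_T, A_{T+1}) of consecutive masks, (4) divide its
area by A_T. The resulting ratio is insensitive to rigid rotation of a
circularly symmetric projection (rotation is microtubule business) but
responds to genuine shape change (actin business), which is exactly the
dissociation the drug conditions probe.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .detect import BinaryMask2D, binarize_dna_projection
from .model import ImageStack4D


@dataclass
class ShapeChangeSeries:
    """Per-frame areas and per-interval XOR ratios for one cell."""

    area_um2: np.ndarray          # A_T, length T
    xor_um2: np.ndarray           # length T-1
    ratio: np.ndarray             # xor / A_T, length T-1

    def __post_init__(self):
        if np.any(self.area_um2 <= 0):
            raise ValueError("binary areas must be positive")
        if np.any(self.xor_um2 < 0) or np.any(self.ratio < 0):
            raise ValueError("XOR areas and ratios must be non-negative")


def shape_change_ratio(mask_t: BinaryMask2D | np.ndarray,
                       mask_t1: BinaryMask2D | np.ndarray,
                       pixel_size_um: float | None = None) -> float:
    """area(XOR(A_T, A_{T+1})) / area(A_T) for two same-grid binary masks.

    Swapping the arguments changes only the denominator:
    ratio(a, b) * area(a) == ratio(b, a) * area(b).
    """
    if isinstance(mask_t, BinaryMask2D):
        a, b = mask_t.mask, (mask_t1.mask if isinstance(mask_t1, BinaryMask2D)
                             else np.asarray(mask_t1, dtype=bool))
    else:
        a = np.asarray(mask_t, dtype=bool)
        b = mask_t1.mask if isinstance(mask_t1, BinaryMask2D) else np.asarray(mask_t1, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("masks must share the same grid")
    na = int(a.sum())
    if na == 0:
        raise ValueError("first mask is empty (division by zero)")
    return float(np.logical_xor(a, b).sum() / na)


def shape_change_series(stack: ImageStack4D, frames=None) -> ShapeChangeSeries:
    """Binarize each frame's DNA projection and compute the XOR ratio series."""
    if frames is None:
        frames = range(stack.n_frames)
    frames = list(frames)
    if len(frames) < 2:
        raise ValueError("need at least two frames")
    masks = []
    for f in frames:
        try:
            masks.append(binarize_dna_projection(stack, f))
        except ValueError as e:
            raise ValueError(f"segmentation failed at frame {f}: {e}") from e
    px2 = masks[0].pixel_size_um ** 2
    areas = np.array([m.mask.sum() * px2 for m in masks])
    xors = np.array([np.logical_xor(masks[i].mask, masks[i + 1].mask).sum() * px2
                     for i in range(len(masks) - 1)])
    return ShapeChangeSeries(area_um2=areas, xor_um2=xors,
                             ratio=xors / areas[:-1])


def oscillation_summary(stacks: list[ImageStack4D],
                        n_intervals: int = 10) -> tuple[float, list[float]]:
    """Mean XOR ratio pooled over cells (default 10 intervals x 5 cells).

    Each stack contributes its first `n_intervals` consecutive ratios; returns
    (pooled mean, all per-interval ratios). Segmentation failures propagate
    with the cell index.
    """
    if not stacks:
        raise ValueError("no cells")
    pooled: list[float] = []
    for ci, stack in enumerate(stacks):
        if stack.n_frames < n_intervals + 1:
            raise ValueError(f"cell {ci}: need >= {n_intervals + 1} frames")
        try:
            series = shape_change_series(stack, range(n_intervals + 1))
        except ValueError as e:
            raise ValueError(f"cell {ci}: {e}") from e
        pooled.extend(series.ratio.tolist())
    return float(np.mean(pooled)), pooled
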