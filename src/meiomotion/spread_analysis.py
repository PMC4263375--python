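"""Fixed-cell quantifications on chromosome spreads and 3D stacks.

Covers the three counting/colocalization readouts: distinct telomeric focus
number (pairing state: 80 before, 40 after full synapsis in mouse), internal
(envelope-detached) telomere number per cell, and the fraction of peripheral
telomeric foci lying on the microtubule-cable network.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import distance_transform_edt

from .detect import (CableSkeleton, FocusDetection, NucleusBoundary,
                     detect_foci_2d, detect_foci_3d, detections_to_array)
from .model import ImageStack4D, SpreadImage


def count_trf1_foci(image: SpreadImage | ImageStack4D, frame: int = 0,
                    merge_um: float = 0.5) -> int:
    """Number of distinct telomeric foci in a spread (or one stack frame).

    Uses the standard spot detector with the optical merge distance, so a
    fully synapsed mouse spread yields 40 and a fully unpaired one 80.
    """
    if isinstance(image, SpreadImage):
        dets = detect_foci_2d(image.channel("TRF1"), image.pixel_size_um,
                              merge_um=merge_um)
    else:
        dets = detect_foci_3d(image, frame, channel="GFP", merge_um=merge_um)
    return len(dets)


def count_internal_telomeres(detections: list[FocusDetection],
                             boundary: NucleusBoundary,
                             margin_um: float = 0.8) -> int:
    """Number of foci strictly inside the nuclear surface.

    A focus is internal iff its signed distance inside the segmented surface
    exceeds `margin_um`. Envelope-attached foci read as slightly inside the
    Otsu surface (threshold bias plus the local envelope protrusion at each
    telomere), up to ~0.6 µm, while genuinely detached telomeres sit > 1.2 µm
    deep; the default margin bisects that gap.
    """
    if not detections:
        return 0
    pts = detections_to_array(detections)
    d = boundary.signed_distance(pts)
    return int(np.sum(d > margin_um))


@dataclass
class ColocalizationResult:
    n_peripheral: int
    n_on_cable: int

    def __post_init__(self):
        if not 0 <= self.n_on_cable <= self.n_peripheral:
            raise ValueError("on-cable count out of range")

    @property
    def ratio(self) -> float:
        return self.n_on_cable / self.n_peripheral


def coloc_ratio(foci: list[FocusDetection] | np.ndarray,
                skeleton: CableSkeleton,
                annulus_mask: np.ndarray | None = None,
                tolerance_um: float = 0.3) -> ColocalizationResult:
    """Fraction of peripheral foci on the cable skeleton.

    A focus counts as on-cable iff the distance from its centroid to the
    nearest skeleton pixel is <= tolerance (default 0.3 µm: the rasterized
    cable half-width plus localization error). When an annulus mask is given,
    only foci inside it (the nuclear periphery) enter the denominator.
    Raises when no peripheral focus remains.
    """
    pts = foci if isinstance(foci, np.ndarray) else detections_to_array(foci)
    if pts.shape[1] == 3:
        pts = pts[:, :2]
    px = skeleton.pixel_size_um
    if annulus_mask is not None and len(pts):
        jj = np.clip((pts[:, 0] / px).astype(int), 0, annulus_mask.shape[1] - 1)
        ii = np.clip((pts[:, 1] / px).astype(int), 0, annulus_mask.shape[0] - 1)
        pts = pts[annulus_mask[ii, jj]]
    if not len(pts):
        raise ValueError("no peripheral foci")
    dist = distance_transform_edt(~skeleton.skeleton) * px
    jj = np.clip((pts[:, 0] / px).astype(int), 0, dist.shape[1] - 1)
    ii = np.clip((pts[:, 1] / px).astype(int), 0, dist.shape[0] - 1)
    on = dist[ii, jj] <= tolerance_um
    return ColocalizationResult(n_peripheral=len(pts), n_on_cable=int(on.sum()))


def aggregate_coloc(results: list[ColocalizationResult]):
    """Multi-cell aggregation: mean of per-cell ratios with SD, plus pooled.

    Returns (mean_ratio, sd, pooled_ratio, n_cells). The per-cell mean is the
    primary figure statistic (error bars are the SD across cells); the pooled
    ratio over all foci is reported alongside.
    """
    if not results:
        raise ValueError("no cells")
    ratios = np.array([r.ratio for r in results])
    pooled = sum(r.n_on_cable for r in results) / sum(r.n_peripheral for r in results)
    return (float(ratios.mean()), float(ratios.std(ddof=1)) if len(ratios) > 1 else 0.0,
            float(pooled), len(results))
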