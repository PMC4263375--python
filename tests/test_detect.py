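"""Detectors: exactness on synthetic truth, localization, masks, cables."""
import numpy as np
import pytest
from scipy.spatial.distance import cdist

import meiomotion as mm
from meiomotion.detect import (binarize_dna_projection, detect_foci_2d,
                               detect_foci_3d, detect_heterochromatin,
                               detections_to_array, nucleus_boundary_3d,
                               segment_cables)
from meiomotion.model import ImageStack4D


def _blank_stack(shape=(1, 2, 8, 64, 64), seed=0):
    rng = np.random.default_rng(seed)
    data = rng.poisson(5.0, size=shape).astype(np.float32)
    return ImageStack4D(data=data, channel_names=("GFP", "DNA"),
                        voxel_size_um=(1.0, 0.1, 0.1), frame_interval_s=7.0)


def test_blank_stack_yields_no_foci():
    assert detect_foci_3d(_blank_stack(), 0) == []


def test_missing_channel_errors(pachytene_stack):
    with pytest.raises(KeyError, match="TRF1"):
        detect_foci_3d(pachytene_stack, 0, channel="TRF1")


def test_detection_exact_and_localized(pachytene_stack, pachytene_truth,
                                       stack_center):
    """All 40 merged sites detected, none spurious, RMSE well under 0.2 µm."""
    dets = detect_foci_3d(pachytene_stack, 0)
    D = detections_to_array(dets)
    sites = np.unique(np.round(pachytene_truth.positions_um[0] + stack_center, 6),
                      axis=0)
    assert len(D) == len(sites) == 40
    d = cdist(sites, D)
    match = d.min(axis=1)
    assert match.max() < 0.2
    err = D[d.argmin(axis=1)] - sites
    assert np.sqrt((err[:, :2] ** 2).sum(axis=1).mean()) < 0.05   # lateral
    assert np.sqrt((err[:, 2] ** 2).mean()) < 0.15                # axial


def test_close_spots_merge():
    """Two spots 0.3 µm apart (below the 0.5 µm merge distance) -> one focus."""
    rng = np.random.default_rng(1)
    img = rng.normal(5, 1, size=(64, 64)).clip(0)
    xs = (np.arange(64) + 0.5) * 0.1
    for x0 in (3.0, 3.3):
        gx = np.exp(-0.5 * ((xs - x0) / 0.15) ** 2)
        gy = np.exp(-0.5 * ((xs - 3.0) / 0.15) ** 2)
        img += 300 * gy[:, None] * gx[None, :]
    dets = detect_foci_2d(img, 0.1)
    assert len(dets) == 1


def test_binarize_sphere_area(sphere_stack):
    """Undeformed nucleus projects to a disk of area ~ pi R^2.

    Otsu thresholds land ~2/3 of the way up the blurred edge profile, so the
    mask is systematically a few percent smaller than the geometric cross
    section; the XOR oscillation statistic divides by A_T and is insensitive
    to this. Assert the area within 5% and the bias direction (never larger).
    """
    m = binarize_dna_projection(sphere_stack, 0)
    assert m.area_um2 == pytest.approx(np.pi * 25.0, rel=0.05)
    assert m.area_um2 <= np.pi * 25.0


def test_binarize_flat_image_errors():
    stack = ImageStack4D(data=np.zeros((1, 2, 4, 32, 32), dtype=np.float32),
                         channel_names=("GFP", "DNA"),
                         voxel_size_um=(1.0, 0.1, 0.1), frame_interval_s=7.0)
    with pytest.raises(ValueError, match="no nucleus"):
        binarize_dna_projection(stack, 0)


def test_binarize_keeps_largest_component():
    data = np.zeros((1, 2, 4, 64, 64), dtype=np.float32)
    data[0, 1, :, 10:30, 10:30] = 100.0    # large nucleus
    data[0, 1, :, 45:45 + 8, 45:45 + 8] = 100.0   # smaller second nucleus
    stack = ImageStack4D(data=data, channel_names=("GFP", "DNA"),
                         voxel_size_um=(1.0, 0.1, 0.1), frame_interval_s=7.0)
    m = binarize_dna_projection(stack, 0, smooth_px=0)
    assert m.mask[20, 20] and not m.mask[49, 49]


def test_binarize_area_rotation_invariant(sphere_stack, sphere_preset):
    """A circularly symmetric nucleus keeps its projected area under rotation."""
    truth2 = mm.simulate_timelapse(sphere_preset, 3, 30.0, seed=9)
    stack2 = mm.render_stack(truth2, seed=9)
    a0 = binarize_dna_projection(stack2, 0).area_um2
    a2 = binarize_dna_projection(stack2, 2).area_um2
    assert abs(a2 - a0) / a0 <= 0.01


def test_boundary_distance_function(sphere_stack, stack_center):
    b = nucleus_boundary_3d(sphere_stack, 0)
    center = np.array(sphere_stack.meta["center_px_offset_um"])
    # centre of a 5 µm sphere: distance ~ R (limited by the 1 µm z sampling
    # at the poles plus the Otsu threshold bias at the lateral edge)
    assert b.signed_distance(center) == pytest.approx(5.0, abs=0.6)
    # a surface point: |distance| within a voxel diagonal
    assert abs(b.signed_distance(center + [5.0, 0, 0])) <= 1.05
    # far outside: negative
    assert b.signed_distance(center + [9.0, 0, 0]) < 0


def test_heterochromatin_blobs_recovered(pachytene_stack, pachytene_truth,
                                         stack_center):
    dets = detect_heterochromatin(pachytene_stack, 0)
    H = detections_to_array(dets)
    truth = pachytene_truth.heterochromatin_um[0] + stack_center
    assert len(H) == len(truth) == 10
    match = cdist(truth, H).min(axis=1)
    assert match.max() < 0.45
    assert np.sqrt((match ** 2).mean()) < 0.3


def test_uniform_nucleus_has_no_blobs(sphere_preset):
    import dataclasses

    p = dataclasses.replace(sphere_preset, n_heterochromatin=3)
    truth = mm.simulate_timelapse(p, 2, 7.0, seed=3)
    import meiomotion.render as rd
    params = rd.RenderParams(blob_amplitude=0.0, ne_bump_amplitude=0.0)
    stack = mm.render_stack(truth, params, seed=3)
    assert detect_heterochromatin(stack, 0) == []


def test_segment_cables_straight_line_midline():
    """A straight 3-px-wide bar skeletonizes to its 1-px midline (±1 px)."""
    from meiomotion.model import SpreadImage

    img = np.full((64, 64), 5.0, dtype=np.float32)
    img[31:34, 8:56] = 200.0
    rng = np.random.default_rng(0)
    img += rng.normal(0, 1, img.shape).astype(np.float32)
    spread = SpreadImage(
        data=np.stack([img, img, img, img]),
        channel_names=("TRF1", "SCP3", "TUBULIN", "DNA"), pixel_size_um=0.1,
        foci_um=np.zeros((0, 2)), on_cable=np.zeros(0, bool),
        peripheral=np.zeros(0, bool), cable_mask=np.zeros((64, 64), bool),
        annulus_mask=np.zeros((64, 64), bool))
    skel = segment_cables(spread, min_size_px=10)
    ys, xs = np.nonzero(skel.skeleton)
    inner = (xs > 12) & (xs < 52)          # away from bar ends
    assert inner.any()
    assert np.all(np.abs(ys[inner] - 32) <= 1)


def test_segment_cables_blank_errors():
    from meiomotion.model import SpreadImage

    flat = np.zeros((4, 32, 32), dtype=np.float32)
    spread = SpreadImage(data=flat,
                         channel_names=("TRF1", "SCP3", "TUBULIN", "DNA"),
                         pixel_size_um=0.1, foci_um=np.zeros((0, 2)),
                         on_cable=np.zeros(0, bool), peripheral=np.zeros(0, bool),
                         cable_mask=np.zeros((32, 32), bool),
                         annulus_mask=np.zeros((32, 32), bool))
    with pytest.raises(ValueError, match="empty"):
        segment_cables(spread)


def test_rendered_cables_capture_on_cable_foci(wt_spread):
    """Every ground-truth on-cable focus lies within tolerance of the skeleton."""
    from scipy.ndimage import distance_transform_edt

    skel = segment_cables(wt_spread)
    assert skel.skeleton.sum() <= skel.mask.sum()
    assert not np.any(skel.skeleton & ~skel.mask)
    d = distance_transform_edt(~skel.skeleton) * wt_spread.pixel_size_um
    ij = (wt_spread.foci_um[:, ::-1] / wt_spread.pixel_size_um).astype(int)
    on = wt_spread.on_cable
    assert np.all(d[ij[on, 0], ij[on, 1]] <= 0.3)
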