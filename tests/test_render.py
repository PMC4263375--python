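"""Renderer: determinism, photometry, error handling."""
import dataclasses

import numpy as np
import pytest

import meiomotion as mm
from meiomotion.render import RenderParams, render_stack


def test_render_deterministic(pachytene_truth):
    a = render_stack(pachytene_truth, seed=7)
    b = render_stack(pachytene_truth, seed=7)
    assert np.array_equal(a.data, b.data)
    c = render_stack(pachytene_truth, seed=8)
    assert not np.array_equal(a.data, c.data)


def test_stack_layout(pachytene_stack):
    assert pachytene_stack.data.ndim == 5
    assert pachytene_stack.channel_names == ("GFP", "DNA")
    assert pachytene_stack.voxel_size_um == (1.0, 0.1, 0.1)
    assert pachytene_stack.frame_interval_s == 7.0
    assert 7 <= pachytene_stack.data.shape[2] <= 12   # optical sections


def test_spot_integrated_intensity_matches_gaussian_integral(pachytene_truth):
    """Without noise, each isolated spot integrates to amp * (2pi)^{3/2}
    * sigma_xy^2 * sigma_z / voxel volume."""
    params = RenderParams(read_noise_sd=0.0, gfp_background=0.0,
                          photon_scale=1.0)
    # noise-free expectation: huge photon scale makes Poisson relative error ~0
    params = dataclasses.replace(params, photon_scale=1e4)
    stack = render_stack(pachytene_truth, params, seed=1)
    gfp = stack.channel("GFP")[0]
    voxel_vol = 0.1 * 0.1 * 1.0
    per_spot = (params.spot_amplitude * (2 * np.pi) ** 1.5
                * params.psf_sigma_xy_um ** 2 * params.psf_sigma_z_um / voxel_vol)
    # 80 telomeres in 40 merged sites -> total = 80 spot equivalents
    assert gfp.sum() == pytest.approx(80 * per_spot, rel=0.02)


def test_empty_truth_is_pure_noise(pachytene_truth):
    empty = dataclasses.replace(
        pachytene_truth,
        positions_um=np.zeros((pachytene_truth.n_frames, 0, 3)),
        pair_id=np.zeros(0, dtype=int), arm_class=np.array([], dtype=object),
        clustered=np.zeros(0, dtype=bool), radial_frac=np.zeros(0),
    )
    stack = render_stack(empty, seed=1)
    gfp = stack.channel("GFP")[0]
    bg = RenderParams().gfp_background
    assert abs(gfp.mean() - bg) < 1.0          # baseline plus noise
    assert gfp.std() < 4 * np.sqrt(bg + RenderParams().read_noise_sd ** 2)


def test_grid_too_small_errors(pachytene_truth):
    with pytest.raises(ValueError, match="grid too small"):
        render_stack(pachytene_truth, RenderParams(fov_xy_um=6.0), seed=1)
    with pytest.raises(ValueError, match="grid too small"):
        render_stack(pachytene_truth, RenderParams(z_slices=7), seed=1)


def test_spread_determinism_and_truth(wt_spread):
    again = mm.render_spread(mm.make_spread_preset("wt"), seed=2)
    assert np.array_equal(wt_spread.data, again.data)
    assert wt_spread.channel_names == ("TRF1", "SCP3", "TUBULIN", "DNA")
    assert len(wt_spread.foci_um) == 25
    assert wt_spread.peripheral.all()


def test_spread_on_cable_foci_touch_cable_mask(wt_spread):
    from scipy.ndimage import distance_transform_edt

    d = distance_transform_edt(~wt_spread.cable_mask) * wt_spread.pixel_size_um
    ij = (wt_spread.foci_um[:, ::-1] / wt_spread.pixel_size_um).astype(int)
    dist = d[ij[:, 0], ij[:, 1]]
    assert dist[wt_spread.on_cable].max() <= 0.2       # on the centreline
    assert dist[~wt_spread.on_cable].min() >= 0.6      # 2x coloc tolerance


def test_spread_off_cable_placement_error():
    crowded = dataclasses.replace(mm.make_spread_preset("sun1_null"),
                                  n_cables=60)
    with pytest.raises(RuntimeError, match="cable density"):
        mm.render_spread(crowded, seed=1)


def test_spread_count_mode_has_no_cables():
    s = mm.render_spread(mm.make_spread_preset("synapsed"), seed=3, mode="count")
    assert not s.cable_mask.any()
    assert len(s.foci_um) == 40
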