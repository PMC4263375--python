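"""Render microscope-like images from simulated ground truth.

Widefield surrogate optics: diffraction-limited spots are anisotropic Gaussians
(default sigma 0.15 µm lateral, 0.5 µm axial), the chromatin (DNA) channel is
the filled deformed-envelope interior with brighter pericentromeric
heterochromatin blobs, and counts are corrupted by Poisson shot noise followed
by additive Gaussian read noise. Neither defocus structure nor photobleaching
is modelled.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from ._sphere import unit
from .model import GroundTruth, ImageStack4D, SpreadImage
from .presets import SpreadPreset, make_spread_preset


@dataclass(frozen=True)
class RenderParams:
    """Physical and noise parameters of the virtual microscope.

    Voxels default to 0.1 x 0.1 x 1.0 µm (x, y, z) with 12 optical sections —
    enough 1 µm sections to cover a 10 µm nucleus, within the 7-12 section
    range used for live imaging. `photon_scale` multiplies all expected counts
    before the Poisson draw; spot/background amplitudes are in expected counts.
    """

    voxel_xy_um: float = 0.1
    voxel_z_um: float = 1.0
    z_slices: int = 12
    fov_xy_um: float | None = None      # None: sized from the ground truth
    psf_sigma_xy_um: float = 0.15
    psf_sigma_z_um: float = 0.5
    spot_amplitude: float = 400.0
    dna_base: float = 60.0
    blob_amplitude: float = 120.0
    blob_sigma_um: float = 0.5
    gfp_background: float = 5.0
    dna_background: float = 10.0
    photon_scale: float = 1.0
    read_noise_sd: float = 2.0
    edge_softness_um: float = 0.12
    # local envelope protrusion rendered at each attached telomere: the
    # LINC-anchored chromosome end deflects the envelope, so chromatin signal
    # bulges with the (microtubule-driven) telomere as it moves
    ne_bump_amplitude: float = 22.0
    ne_bump_sigma_xy_um: float = 0.22
    ne_bump_sigma_z_um: float = 0.4

    def __post_init__(self):
        if self.voxel_xy_um <= 0 or self.voxel_z_um <= 0 or self.z_slices < 1:
            raise ValueError("voxel grid must be positive")


def _grid_axes(params: RenderParams, fov_xy_um: float):
    n_xy = int(np.ceil(fov_xy_um / params.voxel_xy_um))
    xs = (np.arange(n_xy) + 0.5) * params.voxel_xy_um
    zs = (np.arange(params.z_slices) + 0.5) * params.voxel_z_um
    return xs, zs


def _add_spots(img, centers, amps, sxy, sz, xs, zs, cut=4.0):
    """Accumulate anisotropic Gaussian spots into img (Z, Y, X) in place."""
    dx = xs[1] - xs[0] if len(xs) > 1 else 1.0
    dz = zs[1] - zs[0] if len(zs) > 1 else 1.0
    for c, a in zip(centers, amps):
        x0, y0, z0 = c
        ix = np.searchsorted(xs, [x0 - cut * sxy, x0 + cut * sxy])
        iy = np.searchsorted(xs, [y0 - cut * sxy, y0 + cut * sxy])
        iz = np.searchsorted(zs, [z0 - cut * sz, z0 + cut * sz])
        ix = slice(max(ix[0] - 1, 0), min(ix[1] + 1, len(xs)))
        iy = slice(max(iy[0] - 1, 0), min(iy[1] + 1, len(xs)))
        iz = slice(max(iz[0] - 1, 0), min(iz[1] + 1, len(zs)))
        gx = np.exp(-0.5 * ((xs[ix] - x0) / sxy) ** 2)
        gy = np.exp(-0.5 * ((xs[iy] - y0) / sxy) ** 2)
        gz = np.exp(-0.5 * ((zs[iz] - z0) / sz) ** 2)
        img[iz, iy, ix] += a * gz[:, None, None] * gy[None, :, None] * gx[None, None, :]


def render_stack(truth: GroundTruth, params: RenderParams | None = None,
                 seed: int = 0) -> ImageStack4D:
    """Render a two-channel (GFP, DNA) time-lapse stack from ground truth.

    The GFP channel holds one Gaussian spot per telomere (merged pairs add up);
    the DNA channel is the deformed-envelope interior plus heterochromatin
    blobs. Both are corrupted by Poisson then Gaussian noise. A fixed seed
    yields a bit-identical stack.

    Raises ValueError if the voxel grid cannot contain the nucleus.
    """
    params = params or RenderParams()
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x51AC]))

    R = truth.nucleus.radius_um
    amax = 1.0 + truth.nucleus.deform_amplitude + truth.nucleus.static_deform
    need = 2 * (R * amax + 4 * params.psf_sigma_xy_um + 0.5)
    fov = params.fov_xy_um or float(np.ceil(need / 0.8) * 0.8)
    xs, zs = _grid_axes(params, fov)
    if xs[-1] - xs[0] < need - 1.0 or (zs[-1] - zs[0] + params.voxel_z_um) < 2 * R * amax:
        raise ValueError(
            "voxel grid too small to contain the nucleus; increase fov_xy_um / z_slices"
        )
    center = np.array([fov / 2.0, fov / 2.0, params.z_slices * params.voxel_z_um / 2.0])

    T = truth.n_frames
    nz, ny, nx = len(zs), len(xs), len(xs)
    data = np.zeros((T, 2, nz, ny, nx), dtype=np.float32)

    zz, yy, xx = np.meshgrid(zs - center[2], xs - center[1], xs - center[0],
                             indexing="ij")
    rr = np.sqrt(xx ** 2 + yy ** 2 + zz ** 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        dgrid = np.stack([xx / rr, yy / rr, zz / rr], axis=-1)
    dgrid[rr == 0] = (0.0, 0.0, 1.0)

    for f in range(T):
        gfp = np.full((nz, ny, nx), params.gfp_background, dtype=float)
        pos = truth.positions_um[f] + center
        _add_spots(gfp, pos, np.full(len(pos), params.spot_amplitude),
                   params.psf_sigma_xy_um, params.psf_sigma_z_um, xs, zs)

        rb = truth.boundary_radius(dgrid, f) if truth.boundary_radius else R
        interior = 1.0 / (1.0 + np.exp(-(rb - rr) / params.edge_softness_um))
        dna = params.dna_background + params.dna_base * interior
        het = truth.heterochromatin_um[f] + center
        _add_spots(dna, het, np.full(len(het), params.blob_amplitude),
                   params.blob_sigma_um, params.blob_sigma_um, xs, zs)
        if params.ne_bump_amplitude:
            attached = truth.radial_frac >= 1.0
            bumps = truth.positions_um[f][attached] + center
            _add_spots(dna, bumps,
                       np.full(len(bumps), params.ne_bump_amplitude),
                       params.ne_bump_sigma_xy_um, params.ne_bump_sigma_z_um,
                       xs, zs)

        for c, chan in enumerate((gfp, dna)):
            expected = np.maximum(chan * params.photon_scale, 0.0)
            noisy = rng.poisson(expected).astype(np.float64)
            noisy += rng.normal(0.0, params.read_noise_sd, size=noisy.shape)
            data[f, c] = np.maximum(noisy, 0.0) / max(params.photon_scale, 1e-12)

    return ImageStack4D(
        data=data,
        channel_names=("GFP", "DNA"),
        voxel_size_um=(params.voxel_z_um, params.voxel_xy_um, params.voxel_xy_um),
        frame_interval_s=truth.dt_s,
        origin_um=-center,
        meta={
            "axes": "TCZYX",
            "preset": truth.preset_name,
            "drug_mode": truth.drug_mode,
            "seed": truth.seed,
            "center_px_offset_um": center.tolist(),
            "nucleus_radius_um": R,
        },
    )


# --------------------------------------------------------------------------
# 2D spreads

@dataclass(frozen=True)
class SpreadRenderParams:
    psf_sigma_xy_um: float = 0.15
    spot_amplitude: float = 400.0
    cable_amplitude: float = 150.0
    cable_halfwidth_um: float = 0.15
    dna_base: float = 40.0
    background: float = 5.0
    read_noise_sd: float = 2.0
    coloc_tolerance_um: float = 0.3


def _rasterize_curve(mask, pts_um, halfwidth_um, px):
    """Stamp a polyline of sample points into a boolean mask with thickness."""
    ny, nx = mask.shape
    r = max(int(np.ceil(halfwidth_um / px)), 1)
    yy, xx = np.mgrid[-r:r + 1, -r:r + 1]
    disk = (xx ** 2 + yy ** 2) <= (halfwidth_um / px) ** 2 + 0.26
    for x, y in pts_um:
        i, j = int(y / px), int(x / px)
        i0, i1 = max(i - r, 0), min(i + r + 1, ny)
        j0, j1 = max(j - r, 0), min(j + r + 1, nx)
        if i0 >= i1 or j0 >= j1:
            continue
        mask[i0:i1, j0:j1] |= disk[i0 - (i - r): disk.shape[0] - ((i + r + 1) - i1),
                                   j0 - (j - r): disk.shape[1] - ((j + r + 1) - j1)]
    return mask


def _make_cables(rng, preset: SpreadPreset, center, px, shape):
    """Smooth random arcs hugging the NE annulus, as centrelines + raster mask."""
    from scipy.interpolate import CubicSpline

    r_lo, r_hi = preset.annulus_um
    mask = np.zeros(shape, dtype=bool)
    centerlines = []
    for _ in range(preset.n_cables):
        theta0 = rng.uniform(0, 2 * np.pi)
        span = rng.uniform(1.2, 2.4)
        n_ctrl = 6
        th_ctrl = theta0 + np.linspace(0, span, n_ctrl)
        r_ctrl = rng.uniform(r_lo + 0.3, r_hi - 0.3, size=n_ctrl)
        cs = CubicSpline(th_ctrl, r_ctrl)
        th = np.linspace(th_ctrl[0], th_ctrl[-1], int(span * 150))
        rr = np.clip(cs(th), r_lo + 0.1, r_hi - 0.1)
        pts = np.stack([center[0] + rr * np.cos(th),
                        center[1] + rr * np.sin(th)], axis=1)
        centerlines.append(pts)
        _rasterize_curve(mask, pts, 0.15, px)
    return centerlines, mask


def render_spread(preset: SpreadPreset | str, seed: int,
                  params: SpreadRenderParams | None = None,
                  mode: str | None = None) -> SpreadImage:
    """Render one fixed-cell spread with generative ground truth.

    Count-style presets (p_on is None) scatter all distinct telomeric focus
    sites across the flattened nucleus disk with the minimum-separation rule,
    merged homolog ends contributing a single (brighter) site. Colocalization
    presets place `n_peripheral` foci in the NE annulus of a single peripheral
    optical section: a stratified fraction p_on of them on microtubule-cable
    centrelines, the rest at least twice the colocalization tolerance away
    from any cable.

    Raises RuntimeError when off-cable foci cannot be placed (cables too dense).
    """
    if isinstance(preset, str):
        preset = make_spread_preset(preset)
    params = params or SpreadRenderParams()
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x5B12]))

    px = preset.pixel_size_um
    n_px = preset.image_px
    shape = (n_px, n_px)
    extent = n_px * px
    center = np.array([extent / 2.0, extent / 2.0])

    yy, xx = (np.mgrid[0:n_px, 0:n_px] + 0.5) * px
    rr = np.hypot(xx - center[0], yy - center[1])
    r_lo, r_hi = preset.annulus_um
    annulus = (rr >= r_lo) & (rr <= r_hi)
    disk = rr <= preset.nucleus_radius_um

    if mode is None:
        mode = "coloc" if preset.p_on is not None else "count"
    if mode not in ("count", "coloc"):
        raise ValueError("mode must be 'count' or 'coloc'")
    if mode == "coloc" and preset.p_on is None:
        raise ValueError(f"preset {preset.name!r} has no on-cable probability")
    coloc_mode = mode == "coloc"
    if coloc_mode:
        centerlines, cable_mask = _make_cables(rng, preset, center, px, shape)
        foci, on_cable = _place_coloc_foci(rng, preset, params, centerlines,
                                           cable_mask, center, px, shape)
        peripheral = np.ones(len(foci), dtype=bool)
    else:
        cable_mask = np.zeros(shape, dtype=bool)
        foci = _place_count_foci(rng, preset, center)
        on_cable = np.zeros(len(foci), dtype=bool)
        peripheral = np.hypot(*(foci - center).T) >= r_lo

    # amplitudes: merged sites carry two telomere equivalents
    amps = np.full(len(foci), params.spot_amplitude)
    if not coloc_mode and preset.paired_pairs:
        amps[: preset.paired_pairs] *= 2.0

    from scipy.ndimage import gaussian_filter

    trf1 = np.full(shape, params.background, dtype=float)
    xs = (np.arange(n_px) + 0.5) * px
    for (x0, y0), a in zip(foci, amps):
        s = params.psf_sigma_xy_um
        ix = np.searchsorted(xs, [x0 - 4 * s, x0 + 4 * s])
        iy = np.searchsorted(xs, [y0 - 4 * s, y0 + 4 * s])
        sx = slice(max(ix[0] - 1, 0), min(ix[1] + 1, n_px))
        sy = slice(max(iy[0] - 1, 0), min(iy[1] + 1, n_px))
        gx = np.exp(-0.5 * ((xs[sx] - x0) / s) ** 2)
        gy = np.exp(-0.5 * ((xs[sy] - y0) / s) ** 2)
        trf1[sy, sx] += a * gy[:, None] * gx[None, :]

    tub = np.full(shape, params.background, dtype=float)
    tub += gaussian_filter(cable_mask.astype(float), params.psf_sigma_xy_um / px) \
        * params.cable_amplitude
    dna = params.background + params.dna_base * gaussian_filter(
        (disk if not coloc_mode else annulus).astype(float), 2.0)
    scp3 = params.background + 0.3 * params.dna_base * gaussian_filter(
        (disk if not coloc_mode else annulus).astype(float), 4.0)

    chans = []
    for chan in (trf1, scp3, tub, dna):
        noisy = rng.poisson(np.maximum(chan, 0)).astype(float)
        noisy += rng.normal(0, params.read_noise_sd, size=shape)
        chans.append(np.maximum(noisy, 0.0).astype(np.float32))

    return SpreadImage(
        data=np.stack(chans), channel_names=("TRF1", "SCP3", "TUBULIN", "DNA"),
        pixel_size_um=px, foci_um=foci, on_cable=on_cable, peripheral=peripheral,
        cable_mask=cable_mask, annulus_mask=annulus,
        meta={"preset": preset.name, "seed": int(seed),
              "p_on": preset.p_on, "n_sites": preset.n_sites},
    )


def _place_count_foci(rng, preset: SpreadPreset, center, min_sep=1.0,
                      max_tries=40000):
    """All distinct sites uniform in the nucleus disk, min separation enforced."""
    pts: list[np.ndarray] = []
    rad = preset.nucleus_radius_um - 0.4
    tries = 0
    while len(pts) < preset.n_sites:
        if tries > max_tries:
            raise RuntimeError("could not place spread foci; lower the count")
        tries += 1
        r = rad * np.sqrt(rng.uniform())
        th = rng.uniform(0, 2 * np.pi)
        p = center + r * np.array([np.cos(th), np.sin(th)])
        if pts and np.linalg.norm(np.array(pts) - p, axis=1).min() < min_sep:
            continue
        pts.append(p)
    return np.array(pts)


def _place_coloc_foci(rng, preset, params, centerlines, cable_mask, center, px,
                      shape, min_sep=1.0, max_tries=40000):
    """Peripheral foci: stratified p_on on cable centrelines, rest kept clear."""
    from scipy.ndimage import distance_transform_edt

    n = preset.n_peripheral
    frac = preset.p_on * n
    n_on = int(np.floor(frac)) + int(rng.uniform() < (frac - np.floor(frac)))
    clear_um = 2.0 * params.coloc_tolerance_um
    dist_to_cable = distance_transform_edt(~cable_mask) * px

    all_pts = np.concatenate(centerlines)
    pts: list[np.ndarray] = []
    flags: list[bool] = []
    tries = 0
    while len(pts) < n_on:
        if tries > max_tries:
            raise RuntimeError("could not place on-cable foci; add cables")
        tries += 1
        p = all_pts[rng.integers(len(all_pts))]
        p = p + rng.normal(scale=0.02, size=2)   # sub-pixel dither on the line
        if pts and np.linalg.norm(np.array(pts) - p, axis=1).min() < min_sep:
            continue
        pts.append(p)
        flags.append(True)

    r_lo, r_hi = preset.annulus_um
    tries = 0
    while len(pts) < n:
        if tries > max_tries:
            raise RuntimeError(
                "could not place off-cable foci at the required clearance; "
                "lower the cable density"
            )
        tries += 1
        r = rng.uniform(r_lo + 0.2, r_hi - 0.2)
        th = rng.uniform(0, 2 * np.pi)
        p = center + r * np.array([np.cos(th), np.sin(th)])
        i, j = int(p[1] / px), int(p[0] / px)
        if not (0 <= i < shape[0] and 0 <= j < shape[1]):
            continue
        if dist_to_cable[i, j] < clear_um:
            continue
        if pts and np.linalg.norm(np.array(pts) - p, axis=1).min() < min_sep:
            continue
        pts.append(p)
        flags.append(False)
    return np.array(pts), np.array(flags)
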