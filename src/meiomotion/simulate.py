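"""Stage-specific simulation of telomere and nuclear dynamics.

The motion model decomposes chromosome movement into the two superimposed
components seen in live spermatocytes: (i) a persistent great-circle random
walk of each envelope-attached telomere (step length Gamma-distributed, heading
von Mises-persistent — persistence is the model surrogate for rail-tracking
along microtubule cables) and (ii) a rigid unidirectional rotation of the whole
chromatin configuration about a fixed axis. The nuclear envelope is a sphere
deformed by low-order angular modes; an oscillatory (actin-driven) family plus
a small static asphericity that co-rotates with the nucleus. Attached telomeres
ride the deformed surface at all times.

Stage structure is imposed through the presets: merged homolog end pairs
(pachytene), chiasma-tethered pairs with short-arm ends carried by mobile
pericentromeric heterochromatin anchors (diplotene), an MTOC-proximal cap
confining a slowed telomere subset (bouquet), and envelope detachment
(Sun1-null).

Step lengths are calibrated by deterministic simulation so that the *measured*
mean per-interval 3D speed of a preset equals its `v_target` at the requested
sampling interval, whatever the active constraints (rotation, breathing,
excluded volume, tethers) contribute.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _sphere as sph
from .model import ARM_LONG, ARM_SHORT, GroundTruth, NucleusModel, TelomereEnsemble
from .presets import StagePreset, make_stage_preset

DEFAULT_RADIUS_UM = 5.0
INIT_MIN_SEP_UM = 1.0      # dart-throwing separation between distinct sites
RUN_MIN_SEP_UM = 0.7       # excluded-volume floor maintained during stepping
INTERNAL_MAX_FRAC = 0.82   # internal telomeres confined to this radial fraction
SHORT_ARM_MIN_SEP_FACTOR = 0.65   # lower edge of the short-arm separation band
ANCHOR_SPEED_FACTOR = 0.9  # anchor walk speed relative to the free step mean
ANCHOR_JIGGLE_FACTOR = 0.35  # member jiggle about the anchor, same reference
ANCHOR_RADIAL_FRAC = 0.97  # pericentromeric anchors sit just under the NE
BLOB_RADIAL_FRAC = 0.70    # rigid heterochromatin fiducials, clear of the envelope edge
INTERNAL_SPEED_FACTOR = 0.3


# --------------------------------------------------------------------------
# envelope geometry

def _legendre(order: int, x: np.ndarray) -> np.ndarray:
    if order == 2:
        return 0.5 * (3.0 * x * x - 1.0)
    if order == 3:
        return 0.5 * (5.0 * x ** 3 - 3.0 * x)
    raise ValueError(f"unsupported mode order {order}")


def _radius_field(dirs, R, a_static, static_axes, a_dyn, dyn_axes, phases,
                  period, t, orders, coeffs):
    """Envelope radius at unit directions `dirs` and time t (vectorized)."""
    d = np.asarray(dirs, dtype=float)
    out = np.ones(d.shape[:-1])
    for m, (order, c) in enumerate(zip(orders, coeffs)):
        if a_static:
            mu = np.clip(d @ static_axes[m], -1.0, 1.0)
            out = out + a_static * c * _legendre(order, mu)
        if a_dyn:
            mu = np.clip(d @ dyn_axes[m], -1.0, 1.0)
            osc = np.sin(2.0 * np.pi * t / period + phases[m])
            out = out + a_dyn * c * _legendre(order, mu) * osc
    return R * out


def boundary_radius(nucleus: NucleusModel, direction: np.ndarray, t: float) -> np.ndarray:
    """Envelope radius (µm) of `nucleus` along unit `direction` at time t.

    With zero deform amplitudes this is exactly the nuclear radius; the result
    is smooth in both direction and time and bounded by R * (1 + a + a_static).
    """
    return _radius_field(
        direction, nucleus.radius_um, nucleus.static_deform, nucleus.static_axes,
        nucleus.deform_amplitude, nucleus.dynamic_axes, nucleus.dynamic_phases,
        nucleus.deform_period_s, t, nucleus.mode_orders, nucleus.mode_coeffs,
    )


# --------------------------------------------------------------------------
# cell state

@dataclass
class CellState:
    """Full mutable state of one simulated cell.

    `point_um` carries the 3D coordinate of internal (detached) telomeres;
    attached telomeres are defined by their direction and the instantaneous
    envelope radius.
    """

    preset: StagePreset
    nucleus: NucleusModel
    telomeres: TelomereEnsemble
    point_um: np.ndarray                  # (N, 3); used where radial_frac < 1
    hetero_dirs: np.ndarray               # (B, 3)
    hetero_radial: np.ndarray             # (B,)
    hetero_heading: np.ndarray            # (B, 3); anchors walk in diplotene
    hetero_mobile: np.ndarray             # (B,) bool
    time_s: float = 0.0
    step_means_um: tuple[float, float] = field(default=(None, None))  # free, clustered

    @property
    def attached(self) -> np.ndarray:
        return self.telomeres.radial_frac >= 1.0

    def positions(self) -> np.ndarray:
        """Lab-frame telomere coordinates (µm) at the current time."""
        tel = self.telomeres
        r = _boundary_of(self, tel.directions)
        pos = self.nucleus.center_um + r[:, None] * tel.directions
        internal = ~self.attached
        if internal.any():
            pos[internal] = self.nucleus.center_um + self.point_um[internal]
        return pos

    def hetero_positions(self) -> np.ndarray:
        """Heterochromatin blob coordinates (µm); blobs do not breathe."""
        r = self.hetero_radial * self.nucleus.radius_um
        return self.nucleus.center_um + r[:, None] * self.hetero_dirs


def _boundary_of(state: CellState, dirs: np.ndarray) -> np.ndarray:
    return boundary_radius(state.nucleus, dirs, state.time_s)


# --------------------------------------------------------------------------
# initial configuration

AXIAL_LAT_MIN_UM = 0.5     # axially stacked foci need this lateral offset ...
AXIAL_Z_MIN_UM = 2.4       # ... or this much z separation to stay resolvable


def _resolvable(pos, others, min_sep=INIT_MIN_SEP_UM):
    """True when `pos` (µm) is optically distinct from every row of `others`.

    Requires the isotropic minimum separation plus an anti-axial-stacking rule:
    foci closer than AXIAL_LAT_MIN_UM laterally must be at least
    AXIAL_Z_MIN_UM apart in z, otherwise the elongated axial PSF merges them.
    """
    others = np.asarray(others)
    if others.size == 0:
        return True
    d = others.reshape(-1, 3) - np.asarray(pos)
    d3 = np.linalg.norm(d, axis=1)
    dlat = np.linalg.norm(d[:, :2], axis=1)
    dz = np.abs(d[:, 2])
    ok = (d3 >= min_sep) & ((dlat >= AXIAL_LAT_MIN_UM) | (dz >= AXIAL_Z_MIN_UM))
    return bool(ok.all())


def _dart_throw(rng, n, min_chord, radius, max_tries=20000, inside_cap=None):
    """Sample n directions whose sphere positions obey the separation rule."""
    dirs: list[np.ndarray] = []
    tries = 0
    while len(dirs) < n:
        if tries > max_tries:
            raise RuntimeError(
                f"could not place {n} foci with {min_chord:.2f} µm separation on a "
                f"{radius:.1f} µm sphere; use fewer telomeres or a larger radius"
            )
        tries += 1
        if inside_cap is None:
            cand = sph.random_unit_vectors(rng, 1)[0]
        else:
            axis, half = inside_cap
            mu = rng.uniform(np.cos(half), 1.0)
            t1, t2 = sph.tangent_frame(axis[None])
            phi = rng.uniform(0, 2 * np.pi)
            s = np.sqrt(1 - mu * mu)
            cand = mu * axis + s * (np.cos(phi) * t1[0] + np.sin(phi) * t2[0])
        if dirs and not _resolvable(radius * cand, radius * np.array(dirs), min_chord):
            continue
        dirs.append(cand)
    return np.array(dirs)


def init_cell(preset: StagePreset, seed: int,
              radius_um: float = DEFAULT_RADIUS_UM) -> CellState:
    """Build the initial geometric state of one cell for a preset.

    Telomere directions are sampled uniformly on the sphere subject to a
    minimum separation of twice the detector merge distance between distinct
    sites, so rendered focus counts are exact by construction. Bouquet presets
    confine the clustered fraction to a cap around the MTOC direction;
    Sun1-null presets detach `n_internal` telomeres into the nuclear interior.

    Determinism: identical (preset, seed) give identical states.
    """
    if not isinstance(seed, (int, np.integer)):
        raise TypeError("seed must be an explicit integer")
    rng = np.random.default_rng(seed)
    R = float(radius_um)

    nucleus = NucleusModel(
        radius_um=R,
        rotation_axis=sph.random_unit_vectors(rng, 1)[0],
        omega=preset.omega,
        mtoc_dir=sph.random_unit_vectors(rng, 1)[0],
        deform_amplitude=preset.deform_amplitude,
        deform_period_s=preset.deform_period_s,
        static_deform=preset.static_deform,
        stage=preset.name,
        static_axes=sph.random_unit_vectors(rng, 2),
        dynamic_axes=sph.random_unit_vectors(rng, 2),
        dynamic_phases=rng.uniform(0, 2 * np.pi, size=2),
    )

    n = preset.n_telomeres
    pair_id = np.full(n, -1, dtype=int)
    arm_class = np.array([""] * n, dtype=object)
    clustered = np.zeros(n, dtype=bool)
    anchor_index = np.full(n, -1, dtype=int)
    radial_frac = np.ones(n)
    tethered = preset.paired_pairs > 0 and not preset.merged_pairs

    # heterochromatin fiducials / anchors (separation at their actual radius)
    n_blobs = preset.n_heterochromatin
    hetero_dirs = _dart_throw(rng, n_blobs, 1.8 / BLOB_RADIAL_FRAC, R)
    hetero_radial = np.full(n_blobs, BLOB_RADIAL_FRAC)
    hetero_mobile = np.zeros(n_blobs, dtype=bool)
    hetero_heading = sph.random_tangents(rng, hetero_dirs)

    if tethered:
        dirs, pair_id, arm_class, anchor_index, hetero_dirs, hetero_radial, \
            hetero_mobile = _init_tethered(rng, preset, R, n_blobs)
        hetero_heading = sph.random_tangents(rng, hetero_dirs)
    else:
        n_pairs = preset.paired_pairs
        n_singles = n - 2 * n_pairs
        n_sites = n_singles + n_pairs
        n_cluster = int(round(preset.clustered_fraction * n_singles))
        if n_cluster and preset.bouquet_cap_halfangle:
            cap = (nucleus.mtoc_dir, 0.85 * preset.bouquet_cap_halfangle)
            cl_dirs = _dart_throw(rng, n_cluster, INIT_MIN_SEP_UM, R, inside_cap=cap)
            other_dirs = _dart_throw_avoiding(rng, n_sites - n_cluster,
                                              INIT_MIN_SEP_UM, R, cl_dirs)
            site_dirs = np.vstack([cl_dirs, other_dirs])
        else:
            site_dirs = _dart_throw(rng, n_sites, INIT_MIN_SEP_UM, R)
        # site order: clustered singles, free singles, then merged pair sites
        dirs = np.zeros((n, 3))
        singles = np.arange(2 * n_pairs, n)
        clustered[singles[:n_cluster]] = True
        dirs[singles] = site_dirs[:n_singles]
        for pid in range(n_pairs):
            dirs[2 * pid] = dirs[2 * pid + 1] = site_dirs[n_singles + pid]
            pair_id[2 * pid] = pair_id[2 * pid + 1] = pid

    point_um = np.zeros((n, 3))
    if preset.n_internal:
        # detach unpaired telomeres into the interior, keeping 3D separation
        candidates = np.nonzero(pair_id < 0)[0]
        internal_idx = candidates[: preset.n_internal]
        others = R * dirs[np.setdiff1d(np.arange(n), internal_idx)]
        placed = []
        tries = 0
        while len(placed) < preset.n_internal:
            if tries > 20000:
                raise RuntimeError("could not place internal telomeres; lower n_internal")
            tries += 1
            q = rng.uniform(-1, 1, size=3) * R
            frac = np.linalg.norm(q) / R
            if not 0.3 <= frac <= 0.7:
                continue
            ref = np.vstack([others] + [np.array(placed)]) if placed else others
            if not _resolvable(q, ref):
                continue
            placed.append(q)
        for i, q in zip(internal_idx, placed):
            point_um[i] = q
            dirs[i] = sph.unit(q)
            radial_frac[i] = np.linalg.norm(q) / R

    heading = sph.random_tangents(rng, sph.unit(dirs))
    telomeres = TelomereEnsemble(
        directions=sph.unit(dirs), radial_frac=radial_frac, heading=heading,
        pair_id=pair_id, arm_class=arm_class, clustered=clustered,
        anchor_index=anchor_index, merged=preset.merged_pairs,
    )
    return CellState(
        preset=preset, nucleus=nucleus, telomeres=telomeres, point_um=point_um,
        hetero_dirs=hetero_dirs, hetero_radial=hetero_radial,
        hetero_heading=hetero_heading, hetero_mobile=hetero_mobile,
    )


def _dart_throw_avoiding(rng, n, min_chord, radius, existing, max_tries=20000):
    dirs = list(existing)
    out = _dart_throw_with_seedlist(rng, n, min_chord, radius, dirs, max_tries)
    return out


def _dart_throw_with_seedlist(rng, n, min_chord, radius, seeded, max_tries):
    dirs = list(seeded)
    new: list[np.ndarray] = []
    tries = 0
    while len(new) < n:
        if tries > max_tries:
            raise RuntimeError(
                "could not satisfy the minimum-separation rule; "
                "use fewer telomeres or a larger radius"
            )
        tries += 1
        cand = sph.random_unit_vectors(rng, 1)[0]
        if dirs and not _resolvable(radius * cand, radius * np.array(dirs), min_chord):
            continue
        dirs.append(cand)
        new.append(cand)
    return np.array(new)


def _init_tethered(rng, preset: StagePreset, R: float, n_blobs: int):
    """Diplotene layout: 20 short-arm pairs on mobile anchors + 20 long-arm pairs."""
    n = preset.n_telomeres
    n_pairs = preset.paired_pairs
    n_short = n_pairs // 2
    n_long = n_pairs - n_short
    d_s = preset.d_short_um
    d_l = preset.d_long_um

    anchors = _dart_throw(rng, n_short, max(1.5, d_s + 0.6), R)
    dirs = np.zeros((n, 3))
    pair_id = np.full(n, -1, dtype=int)
    arm_class = np.array([""] * n, dtype=object)
    anchor_index = np.full(n, -1, dtype=int)

    for pid in range(n_short):
        t = sph.random_tangents(rng, anchors[pid][None])[0]
        half = 0.5 * rng.uniform(SHORT_ARM_MIN_SEP_FACTOR * d_s, 0.95 * d_s) / R
        a, _ = sph.geodesic_step(anchors[pid], t, half)
        b, _ = sph.geodesic_step(anchors[pid], -t, half)
        i, j = 2 * pid, 2 * pid + 1
        dirs[i], dirs[j] = a, b
        pair_id[i] = pair_id[j] = pid
        arm_class[i] = arm_class[j] = ARM_SHORT
        anchor_index[i] = anchor_index[j] = pid

    taken = [dirs[i] for i in range(2 * n_short)]
    for pid in range(n_short, n_short + n_long):
        while True:
            a = sph.random_unit_vectors(rng, 1)[0]
            if _resolvable(R * a, R * np.array(taken)):
                break
        t = sph.random_tangents(rng, a[None])[0]
        sep = rng.uniform(INIT_MIN_SEP_UM, 0.8 * d_l)
        b, _ = sph.geodesic_step(a, t, sep / R)
        tries = 0
        while not _resolvable(R * b, R * np.array(taken + [a])):
            tries += 1
            if tries > 500:
                break
            t = sph.random_tangents(rng, a[None])[0]
            sep = rng.uniform(INIT_MIN_SEP_UM, 0.8 * d_l)
            b, _ = sph.geodesic_step(a, t, sep / R)
        i, j = 2 * pid, 2 * pid + 1
        dirs[i], dirs[j] = a, b
        pair_id[i] = pair_id[j] = pid
        arm_class[i] = arm_class[j] = ARM_LONG
        taken += [a, b]

    hetero_dirs = anchors
    hetero_radial = np.full(n_short, ANCHOR_RADIAL_FRAC)
    hetero_mobile = np.ones(n_short, dtype=bool)
    if n_blobs > n_short:
        extra = _dart_throw_with_seedlist(rng, n_blobs - n_short, 1.5, R,
                                          list(anchors), 20000)
        hetero_dirs = np.vstack([anchors, extra])
        hetero_radial = np.concatenate([hetero_radial,
                                        np.full(len(extra), BLOB_RADIAL_FRAC)])
        hetero_mobile = np.concatenate([hetero_mobile,
                                        np.zeros(len(extra), dtype=bool)])
    return (dirs, pair_id, arm_class, anchor_index,
            hetero_dirs, hetero_radial, hetero_mobile)


# --------------------------------------------------------------------------
# stepping

def _gamma_steps(rng, mean_um, cv, size):
    if mean_um <= 0:
        return np.zeros(size)
    shape = 1.0 / (cv * cv)
    return rng.gamma(shape, mean_um / shape, size=size)


def _unique_site_leaders(tel: TelomereEnsemble) -> np.ndarray:
    """Indices of distinct optical sites (merged pairs contribute one leader)."""
    if not tel.merged:
        return np.arange(tel.n)
    lead = np.ones(tel.n, dtype=bool)
    seen: set[int] = set()
    for i in range(tel.n):
        pid = tel.pair_id[i]
        if pid >= 0:
            if pid in seen:
                lead[i] = False
            else:
                seen.add(int(pid))
    return np.nonzero(lead)[0]


def _repel(dirs, active_idx, pair_id, R, min_chord, iters=4):
    """Push distinct sites apart to an excluded-volume floor (same-pair exempt)."""
    idx = np.asarray(active_idx)
    for _ in range(iters):
        p = R * dirs[idx]
        diff = p[:, None, :] - p[None, :, :]
        d = np.linalg.norm(diff, axis=-1)
        same_pair = (pair_id[idx][:, None] >= 0) & \
                    (pair_id[idx][:, None] == pair_id[idx][None, :])
        np.fill_diagonal(d, np.inf)
        d[same_pair] = np.inf
        close = d < min_chord
        if not close.any():
            break
        ii, jj = np.nonzero(np.triu(close, k=1))
        for a, b in zip(ii, jj):
            ia, ib = idx[a], idx[b]
            deficit_ang = (min_chord - d[a, b]) / R
            dirs[ib] = sph.slerp_toward(dirs[ib][None], dirs[ia][None],
                                        np.array([-0.5 * deficit_ang]))[0]
            dirs[ia] = sph.slerp_toward(dirs[ia][None], dirs[ib][None],
                                        np.array([-0.5 * deficit_ang]))[0]
    return dirs


def _reflect_into_cap(dirs, mask, axis, half):
    ang = sph.angular_distance(dirs[mask], axis)
    out = ang > half
    if out.any():
        sub = dirs[mask]
        excess = np.zeros_like(ang)
        excess[out] = np.minimum(2 * (ang[out] - half), ang[out] - 0.02)
        sub = sph.slerp_toward(sub, np.broadcast_to(axis, sub.shape), excess)
        dirs[mask] = sub
    return dirs


def step_interval(state: CellState, dt: float, rng: np.random.Generator) -> CellState:
    """Advance the cell by one sampling interval of length dt (seconds).

    Envelope-attached telomeres take one great-circle step (Gamma arc length,
    von Mises-persistent heading); clustered telomeres use the slower clustered
    step and are reflected back into the MTOC cap; diplotene short-arm pairs
    ride their heterochromatin anchor and stay inside the short-arm separation
    band, long-arm pairs are pulled back whenever their 3D separation would
    exceed the long-arm cap; internal telomeres take confined 3D Gaussian
    steps. Finally the whole chromatin configuration (telomeres, blobs,
    envelope mode axes — not the MTOC) rotates rigidly by omega * dt.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    preset = state.preset
    L_free, L_clustered = _step_means(state, dt)
    tel = state.telomeres
    nuc = state.nucleus
    R = nuc.radius_um
    state.time_s += dt

    attached = state.attached
    leaders = _unique_site_leaders(tel)
    lead_attached = leaders[attached[leaders]]
    short_arm = np.array([a == ARM_SHORT for a in tel.arm_class])
    is_anchor_member = short_arm & (tel.anchor_index >= 0)

    # -- mobile heterochromatin anchors walk first (diplotene)
    if state.hetero_mobile.any():
        m = state.hetero_mobile
        old = state.hetero_dirs[m].copy()
        arcs = _gamma_steps(rng, ANCHOR_SPEED_FACTOR * L_free, preset.speed_cv,
                            m.sum()) / R
        nd, nh = sph.geodesic_step(state.hetero_dirs[m], state.hetero_heading[m], arcs)
        turn = sph.von_mises_angles(rng, preset.kappa, m.sum())
        cross = np.cross(nd, nh)
        nh = nh * np.cos(turn)[:, None] + cross * np.sin(turn)[:, None]
        state.hetero_dirs[m] = nd
        state.hetero_heading[m] = sph.unit(nh - nd * np.sum(nh * nd, axis=-1, keepdims=True))
        # transport tethered members rigidly with their anchor
        for k, (o, d) in enumerate(zip(old, state.hetero_dirs[np.nonzero(m)[0]])):
            members = np.nonzero(tel.anchor_index == k)[0]
            if not len(members):
                continue
            axis = np.cross(o, d)
            s = np.linalg.norm(axis)
            if s < 1e-12:
                continue
            ang = np.arcsin(np.clip(s, -1, 1))
            if np.dot(o, d) < 0:
                ang = np.pi - ang
            tel.directions[members] = sph.rotate_about(
                tel.directions[members], axis / s, ang)
            tel.heading[members] = sph.rotate_about(tel.heading[members], axis / s, ang)

    # -- individual steps for attached sites (Gamma arc lengths, per-class mean)
    means = np.full(len(lead_attached), L_free)
    means[tel.clustered[lead_attached]] = L_clustered
    means[is_anchor_member[lead_attached]] = ANCHOR_JIGGLE_FACTOR * L_free
    shape = 1.0 / (preset.speed_cv ** 2)
    arcs = rng.gamma(shape, 1.0, size=len(lead_attached)) * means / shape / R
    nd, nh = sph.geodesic_step(tel.directions[lead_attached],
                               tel.heading[lead_attached], arcs)
    turn = sph.von_mises_angles(rng, preset.kappa, len(lead_attached))
    cross = np.cross(nd, nh)
    nh = nh * np.cos(turn)[:, None] + cross * np.sin(turn)[:, None]
    tel.directions[lead_attached] = nd
    tel.heading[lead_attached] = sph.unit(
        nh - nd * np.sum(nh * nd, axis=-1, keepdims=True))

    # -- internal telomeres: confined 3D Gaussian steps
    internal = ~attached
    if internal.any():
        sigma = INTERNAL_SPEED_FACTOR * preset.v_target * dt / 1.596
        q = state.point_um[internal] + rng.normal(scale=sigma, size=(internal.sum(), 3))
        rmax = INTERNAL_MAX_FRAC * R
        norm = np.linalg.norm(q, axis=1)
        over = norm > rmax
        if over.any():    # radial reflection at the confinement shell
            q[over] *= ((2 * rmax - norm[over]) / norm[over])[:, None]
        state.point_um[internal] = q
        tel.directions[internal] = sph.unit(q)
        tel.radial_frac[internal] = np.minimum(
            np.linalg.norm(q, axis=1) / R, 0.999)

    # -- excluded volume between distinct sites
    if L_free > 0 or state.hetero_mobile.any():
        tel.directions = _repel(tel.directions, lead_attached, tel.pair_id,
                                R, RUN_MIN_SEP_UM)

    # -- bouquet cap containment (after repulsion, so the cap always wins)
    if preset.bouquet_cap_halfangle and tel.clustered.any():
        tel.directions = _reflect_into_cap(
            tel.directions, tel.clustered, nuc.mtoc_dir,
            preset.bouquet_cap_halfangle)

    # -- tether constraints (positions include the instantaneous envelope)
    if preset.paired_pairs and not preset.merged_pairs:
        _enforce_tethers(state)

    # -- merged pairs follow their leader exactly
    if tel.merged and preset.paired_pairs:
        for pid in range(preset.paired_pairs):
            i, j = 2 * pid, 2 * pid + 1
            tel.directions[j] = tel.directions[i]
            tel.heading[j] = tel.heading[i]

    # -- constraint projections moved directions without their headings:
    # re-orthonormalize so the next geodesic step stays on the sphere
    tel.directions = sph.unit(tel.directions)
    h = tel.heading - tel.directions * np.sum(
        tel.heading * tel.directions, axis=-1, keepdims=True)
    hn = np.linalg.norm(h, axis=-1, keepdims=True)
    degenerate = hn[:, 0] < 1e-9
    if degenerate.any():
        t1, _ = sph.tangent_frame(tel.directions[degenerate])
        h[degenerate] = t1
        hn = np.linalg.norm(h, axis=-1, keepdims=True)
    tel.heading = h / hn

    # -- rigid rotation of the whole configuration (not the MTOC)
    ang = nuc.omega * dt
    if ang != 0.0:
        axis = nuc.rotation_axis
        tel.directions = sph.rotate_about(tel.directions, axis, ang)
        tel.heading = sph.rotate_about(tel.heading, axis, ang)
        state.point_um = sph.rotate_about(state.point_um, axis, ang)
        state.hetero_dirs = sph.rotate_about(state.hetero_dirs, axis, ang)
        state.hetero_heading = sph.rotate_about(state.hetero_heading, axis, ang)
        nuc.static_axes = sph.rotate_about(nuc.static_axes, axis, ang)
        nuc.dynamic_axes = sph.rotate_about(nuc.dynamic_axes, axis, ang)
        if preset.bouquet_cap_halfangle and tel.clustered.any():
            tel.directions = _reflect_into_cap(
                tel.directions, tel.clustered, nuc.mtoc_dir,
                preset.bouquet_cap_halfangle)
    return state


def _enforce_tethers(state: CellState, iters: int = 8):
    """Keep short-arm pairs inside their band and long-arm pairs under the cap."""
    preset = state.preset
    tel = state.telomeres
    R = state.nucleus.radius_um
    d_s, d_l = preset.d_short_um, preset.d_long_um
    s_min = SHORT_ARM_MIN_SEP_FACTOR * d_s

    pairs = _pairs(tel)
    ii = np.array([v[0] for v in pairs.values()])
    jj = np.array([v[1] for v in pairs.values()])
    short = np.array([tel.arm_class[i] == ARM_SHORT for i in ii])
    cap = np.where(short, d_s, d_l)
    anchors = tel.anchor_index[ii]

    for _ in range(iters):
        pos = state.positions()
        d = np.linalg.norm(pos[ii] - pos[jj], axis=1)
        over = d > cap
        under = short & (d < s_min)
        # signed slerp angle: positive pulls partners together, negative apart
        ang = np.zeros(len(ii))
        ang[over] = 0.55 * (d[over] - 0.97 * cap[over]) / R
        ang[under] = -0.55 * (s_min - d[under] + 0.02) / R
        if np.any(ang != 0.0):
            ui, uj = tel.directions[ii], tel.directions[jj]
            tel.directions[ii] = sph.slerp_toward(ui, uj, ang)
            tel.directions[jj] = sph.slerp_toward(uj, ui, ang)
        # soft re-centering on the anchor keeps short-arm pairs on their blob
        if short.any():
            allow = 0.7 * d_s / R
            for members in (ii[short], jj[short]):
                a_dirs = state.hetero_dirs[anchors[short]]
                u = tel.directions[members]
                off = sph.angular_distance(u, a_dirs)
                fix = np.maximum(0.0, 0.5 * (off - allow))
                if fix.any():
                    tel.directions[members] = sph.slerp_toward(u, a_dirs, fix)
        if not (over.any() or under.any()):
            break


def _pairs(tel: TelomereEnsemble) -> dict[int, tuple[int, int]]:
    out = {}
    for pid in np.unique(tel.pair_id[tel.pair_id >= 0]):
        i, j = np.nonzero(tel.pair_id == pid)[0]
        out[int(pid)] = (int(i), int(j))
    return out


# --------------------------------------------------------------------------
# speed calibration

_CAL_CACHE: dict[tuple, tuple[float, float]] = {}


def _step_means(state: CellState, dt: float) -> tuple[float, float]:
    if state.step_means_um[0] is not None:
        return state.step_means_um
    means = calibrated_step_means(state.preset, state.nucleus.radius_um, dt)
    state.step_means_um = means
    return means


# stages whose velocity is read out through the tracing protocol
# (detect/link/select); their calibration goes through the same operator
_PROTOCOL_STAGES = frozenset({"leptozygotene", "pachytene", "diplotene"})


def optical_merge_sites(pts: np.ndarray, d_merge_um: float = 0.5,
                        lat_um: float = 0.4, z_um: float = 1.8) -> np.ndarray:
    """Collapse ground-truth sites the widefield optics cannot resolve.

    Sites closer than the detector merge distance in 3D — or laterally
    coincident within `lat_um` and axially within `z_um` (the elongated PSF) —
    are replaced by their connected-component centroid, mimicking what the
    spot detector reports on the rendered image.
    """
    from scipy.sparse import coo_matrix
    from scipy.sparse.csgraph import connected_components

    pts = np.unique(np.round(np.asarray(pts, dtype=float), 9), axis=0)
    n = len(pts)
    if n < 2:
        return pts
    d = pts[:, None, :] - pts[None, :, :]
    d3 = np.linalg.norm(d, axis=-1)
    dlat = np.linalg.norm(d[..., :2], axis=-1)
    dz = np.abs(d[..., 2])
    fuse = (d3 < d_merge_um) | ((dlat < lat_um) & (dz < z_um))
    ncomp, labels = connected_components(coo_matrix(fuse), directed=False)
    out = np.zeros((ncomp, 3))
    for k in range(ncomp):
        out[k] = pts[labels == k].mean(axis=0)
    return out


def _measure_protocol_speed(preset, R, dt, L_free, L_clustered,
                            n_cells=8, n_frames=11, n_tracks=5,
                            n_intervals=10, cal_seed=9173):
    """Mean speed as the tracing protocol measures it, on exact coordinates.

    Simulates cells, collapses optically unresolvable sites, links the
    per-frame positions with the standard gated Hungarian linker, selects
    tracks with 10 continuous intervals (longest first) and pools their
    interval speeds — the same association operator the imaging pipeline
    applies, minus rendering noise.
    """
    from .motion import interval_velocities
    from .tracking import link_tracks, select_traceable

    gate = max(3.0 * preset.v_target * dt, 1.0)
    speeds: list[float] = []
    for c in range(n_cells):
        st = init_cell(preset, cal_seed + c, radius_um=R)
        st.step_means_um = (L_free, L_clustered)
        rng = np.random.default_rng(cal_seed + 1000 + c)
        frames = [optical_merge_sites(st.positions())]
        for _ in range(n_frames - 1):
            step_interval(st, dt, rng)
            frames.append(optical_merge_sites(st.positions()))
        tracks = select_traceable(link_tracks(frames, gate), n_intervals)
        tracks.sort(key=lambda t: (-t.n_frames, t.track_id))
        for t in tracks[:n_tracks]:
            speeds.extend(s.v_um_s for s in interval_velocities(t, dt))
    return float(np.mean(speeds)) if speeds else 0.0


def _measure_mean_speed(preset, R, dt, L_free, L_clustered, group,
                        n_cells=3, n_intervals=16, cal_seed=9173):
    speeds = []
    for c in range(n_cells):
        st = init_cell(preset, cal_seed + c, radius_um=R)
        st.step_means_um = (L_free, L_clustered)
        rng = np.random.default_rng(cal_seed + 1000 + c)
        if group == "clustered":
            sel = st.telomeres.clustered
        else:
            sel = st.attached & ~st.telomeres.clustered
        prev = st.positions()
        for _ in range(n_intervals):
            step_interval(st, dt, rng)
            cur = st.positions()
            speeds.append(np.linalg.norm(cur[sel] - prev[sel], axis=1) / dt)
            prev = cur
    return float(np.mean(np.concatenate(speeds)))


def calibrated_step_means(preset: StagePreset, radius_um: float,
                          dt: float) -> tuple[float, float]:
    """Free and clustered step-length means (µm) hitting the preset's targets.

    Solved by bisection on deterministic pilot simulations (common random
    numbers), so the expected *measured* per-interval speed — including
    rotation, envelope breathing, excluded volume and tether projections —
    equals v_target (and clustered_v_target) at this sampling interval.
    """
    key = (preset, round(radius_um, 6), round(dt, 6))
    if key in _CAL_CACHE:
        return _CAL_CACHE[key]

    protocol = preset.name in _PROTOCOL_STAGES

    def solve(target, group, L_free_fixed=None):
        if target <= 0:
            return 0.0
        lo, hi = 0.2 * target * dt, 3.0 * target * dt
        for _ in range(14):
            mid = 0.5 * (lo + hi)
            if group == "clustered":
                m = _measure_mean_speed(preset, radius_um, dt, L_free_fixed, mid, group)
            elif protocol:
                m = _measure_protocol_speed(preset, radius_um, dt, mid, 0.0)
            else:
                m = _measure_mean_speed(preset, radius_um, dt, mid, 0.0, group)
            if m < target:
                lo = mid
            else:
                hi = mid
        return 0.5 * (lo + hi)

    L_free = solve(preset.v_target, "free")
    L_clustered = solve(preset.clustered_v_target, "clustered", L_free)
    _CAL_CACHE[key] = (L_free, L_clustered)
    return L_free, L_clustered


# --------------------------------------------------------------------------
# time-lapse driver

def simulate_timelapse(preset: StagePreset | str, n_frames: int, dt: float,
                       seed: int, radius_um: float = DEFAULT_RADIUS_UM) -> GroundTruth:
    """Simulate one cell and export per-frame ground truth.

    Returns coordinates of every telomere and heterochromatin blob at each of
    `n_frames` frames sampled every `dt` seconds, the fixed lab-frame MTOC
    coordinate, the pair/cluster tables, and a per-frame envelope radius
    function. Identical (preset, seed) inputs give identical output.
    """
    if isinstance(preset, str):
        preset = make_stage_preset(preset)
    if n_frames < 2:
        raise ValueError("need at least two frames")
    state = init_cell(preset, seed, radius_um=radius_um)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xC0FFEE]))

    T, N, B = n_frames, preset.n_telomeres, len(state.hetero_dirs)
    pos = np.zeros((T, N, 3))
    het = np.zeros((T, B, 3))
    static_axes = np.zeros((T, 2, 3))
    dyn_axes = np.zeros((T, 2, 3))
    pos[0] = state.positions()
    het[0] = state.hetero_positions()
    static_axes[0] = state.nucleus.static_axes
    dyn_axes[0] = state.nucleus.dynamic_axes
    for f in range(1, T):
        step_interval(state, dt, rng)
        pos[f] = state.positions()
        het[f] = state.hetero_positions()
        static_axes[f] = state.nucleus.static_axes
        dyn_axes[f] = state.nucleus.dynamic_axes

    nuc = state.nucleus
    times = np.arange(T) * float(dt)

    def radius_fn(dirs: np.ndarray, frame: int) -> np.ndarray:
        return _radius_field(
            dirs, nuc.radius_um, nuc.static_deform, static_axes[frame],
            nuc.deform_amplitude, dyn_axes[frame], nuc.dynamic_phases,
            nuc.deform_period_s, times[frame], nuc.mode_orders, nuc.mode_coeffs,
        )

    return GroundTruth(
        times_s=times, positions_um=pos, heterochromatin_um=het,
        mtoc_um=nuc.mtoc_um, nucleus=nuc,
        pair_id=state.telomeres.pair_id.copy(),
        arm_class=state.telomeres.arm_class.copy(),
        clustered=state.telomeres.clustered.copy(),
        radial_frac=state.telomeres.radial_frac.copy(),
        preset_name=preset.name, drug_mode=preset.drug_mode,
        seed=int(seed), dt_s=float(dt), boundary_radius=radius_fn,
    )
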