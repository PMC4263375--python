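"""Domain containers: nucleus state, telomere ensemble, ground truth, images.

Coordinate convention (shared by every module): physical micrometres, x = image
column, y = row, z = slice; voxel centres sit at (i + 0.5) * voxel_size.
Simulated ground truth lives in a nucleus-centred frame (centre at the origin);
the renderer records the offset between that frame and the image frame in the
stack metadata.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from ._sphere import unit

ARM_SHORT = "short"
ARM_LONG = "long"


@dataclass
class NucleusModel:
    """Geometric state of one simulated spermatocyte nucleus.

    The envelope is a sphere of radius `radius_um` deformed by low-order angular
    modes: a small static asphericity (amplitude `static_deform`) plus
    oscillatory modes (amplitude `deform_amplitude`, period `deform_period_s`).
    Mode axes co-rotate with the nucleus; the MTOC sits on the cytoplasmic side
    at centre + 1.05 R * mtoc_dir and does not rotate with the chromatin.
    """

    radius_um: float
    rotation_axis: np.ndarray
    omega: float                      # rad/s
    mtoc_dir: np.ndarray
    deform_amplitude: float
    deform_period_s: float
    static_deform: float
    stage: str
    center_um: np.ndarray = field(default_factory=lambda: np.zeros(3))
    # one axis + phase per mode, for the static and the oscillatory family
    static_axes: np.ndarray = field(default_factory=lambda: np.zeros((0, 3)))
    dynamic_axes: np.ndarray = field(default_factory=lambda: np.zeros((0, 3)))
    dynamic_phases: np.ndarray = field(default_factory=lambda: np.zeros(0))
    mode_orders: tuple[int, ...] = (2, 3)
    mode_coeffs: tuple[float, ...] = (0.65, 0.35)

    def __post_init__(self):
        if self.radius_um <= 0:
            raise ValueError("radius must be positive")
        if self.deform_amplitude < 0 or self.deform_amplitude + self.static_deform >= 0.3:
            raise ValueError("deform amplitude out of range (a >= 0, a + a_static < 0.3)")
        self.rotation_axis = unit(np.asarray(self.rotation_axis, dtype=float))
        self.mtoc_dir = unit(np.asarray(self.mtoc_dir, dtype=float))
        self.center_um = np.asarray(self.center_um, dtype=float)

    @property
    def mtoc_um(self) -> np.ndarray:
        """Lab-frame MTOC coordinate (µm)."""
        return self.center_um + 1.05 * self.radius_um * self.mtoc_dir


@dataclass
class TelomereEnsemble:
    """Vectorized per-telomere state for one cell.

    `directions` are unit vectors from the nucleus centre; envelope-attached
    telomeres (radial_frac == 1) sit exactly on the deformed surface, internal
    ones at radial_frac * local envelope radius. `pair_id` is -1 for unpaired
    telomeres and symmetric otherwise; `anchor_index` ties diplotene short-arm
    pairs to a heterochromatin anchor (-1 elsewhere).
    """

    directions: np.ndarray            # (N, 3)
    radial_frac: np.ndarray           # (N,)
    heading: np.ndarray               # (N, 3) unit tangents
    pair_id: np.ndarray               # (N,) int, -1 = unpaired
    arm_class: np.ndarray             # (N,) object: "short"/"long"/""
    clustered: np.ndarray             # (N,) bool
    anchor_index: np.ndarray          # (N,) int, -1 = none
    merged: bool = True               # paired partners co-located?

    def __post_init__(self):
        self.validate()

    def validate(self):
        n = len(self.directions)
        for name in ("radial_frac", "heading", "pair_id", "arm_class",
                     "clustered", "anchor_index"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"field {name} length mismatch")
        paired = self.pair_id >= 0
        if paired.any():
            ids, counts = np.unique(self.pair_id[paired], return_counts=True)
            if not np.all(counts == 2):
                raise ValueError("every pair_id must have exactly two members")

    @property
    def n(self) -> int:
        return len(self.directions)

    def partner_of(self) -> np.ndarray:
        """Index of the pair partner for each telomere (-1 if unpaired)."""
        out = np.full(self.n, -1, dtype=int)
        for pid in np.unique(self.pair_id[self.pair_id >= 0]):
            i, j = np.nonzero(self.pair_id == pid)[0]
            out[i], out[j] = j, i
        return out


@dataclass
class GroundTruth:
    """Exported truth of one simulated time-lapse.

    positions_um has shape (T, N, 3) in the nucleus-centred lab frame;
    heterochromatin_um is (T, B, 3); mtoc_um is fixed in the lab frame.
    `boundary_radius` maps (directions (..., 3), frame index) -> envelope radius
    in µm, sampled at the exported frame times.
    """

    times_s: np.ndarray
    positions_um: np.ndarray
    heterochromatin_um: np.ndarray
    mtoc_um: np.ndarray
    nucleus: NucleusModel
    pair_id: np.ndarray
    arm_class: np.ndarray
    clustered: np.ndarray
    radial_frac: np.ndarray
    preset_name: str
    drug_mode: str
    seed: int
    dt_s: float
    boundary_radius: Callable[[np.ndarray, int], np.ndarray] | None = None

    def __post_init__(self):
        T = len(self.times_s)
        if self.positions_um.shape[0] != T or self.heterochromatin_um.shape[0] != T:
            raise ValueError("frame count inconsistent across exported arrays")
        if not (np.all(np.isfinite(self.positions_um))
                and np.all(np.isfinite(self.heterochromatin_um))):
            raise ValueError("non-finite coordinates in ground truth")
        if T > 1:
            dts = np.diff(self.times_s)
            if not np.allclose(dts, self.dt_s):
                raise ValueError("frame times inconsistent with dt")

    @property
    def n_frames(self) -> int:
        return len(self.times_s)

    @property
    def n_telomeres(self) -> int:
        return self.positions_um.shape[1]

    def pair_table(self) -> dict[int, tuple[int, int]]:
        """pair_id -> (index_a, index_b)."""
        out: dict[int, tuple[int, int]] = {}
        for pid in np.unique(self.pair_id[self.pair_id >= 0]):
            i, j = np.nonzero(self.pair_id == pid)[0]
            out[int(pid)] = (int(i), int(j))
        return out


@dataclass
class ImageStack4D:
    """Rendered multi-channel time-lapse, axes (T, C, Z, Y, X).

    voxel_size_um is (z, y, x); `origin_um` is the lab-frame coordinate of the
    array origin corner, i.e. lab = array_µm + origin_um.
    """

    data: np.ndarray
    channel_names: tuple[str, ...]
    voxel_size_um: tuple[float, float, float]
    frame_interval_s: float
    origin_um: np.ndarray = field(default_factory=lambda: np.zeros(3))
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.data.ndim != 5:
            raise ValueError("stack must have axes (T, C, Z, Y, X)")
        if len(self.channel_names) != self.data.shape[1]:
            raise ValueError("channel name count mismatch")
        if any(v <= 0 for v in self.voxel_size_um):
            raise ValueError("voxel sizes must be positive")

    def channel(self, name: str) -> np.ndarray:
        """(T, Z, Y, X) view of one channel; KeyError lists valid names."""
        try:
            c = self.channel_names.index(name)
        except ValueError:
            raise KeyError(
                f"channel {name!r} not in stack (have {self.channel_names})"
            ) from None
        return self.data[:, c]

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]


@dataclass
class SpreadImage:
    """Rendered 2D spread, axes (C, Y, X), with generative ground truth."""

    data: np.ndarray
    channel_names: tuple[str, ...]
    pixel_size_um: float
    foci_um: np.ndarray               # (n, 2) ground-truth focus (x, y) µm
    on_cable: np.ndarray              # (n,) bool
    peripheral: np.ndarray            # (n,) bool: inside NE annulus
    cable_mask: np.ndarray            # (Y, X) bool
    annulus_mask: np.ndarray          # (Y, X) bool
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.pixel_size_um <= 0:
            raise ValueError("pixel size must be positive")
        ny, nx = self.data.shape[-2:]
        if len(self.foci_um):
            x, y = self.foci_um[:, 0], self.foci_um[:, 1]
            if (x.min() < 0 or y.min() < 0
                    or x.max() > nx * self.pixel_size_um
                    or y.max() > ny * self.pixel_size_um):
                raise ValueError("ground-truth focus outside the image")

    def channel(self, name: str) -> np.ndarray:
        try:
            c = self.channel_names.index(name)
        except ValueError:
            raise KeyError(
                f"channel {name!r} not in spread (have {self.channel_names})"
            ) from None
        return self.data[c]
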