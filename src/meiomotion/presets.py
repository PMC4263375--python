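"""Named parameter bundles for the stage-specific simulations.

A :class:`StagePreset` fixes the motion statistics, pairing/clustering layout and
nuclear-shape dynamics of one meiotic sub-stage (or mutant) of mouse
spermatocytes; a drug mode modifies it the way the corresponding inhibitor acts
in culture (nocodazole destabilizes microtubules and abolishes telomere motion
and nuclear rotation; cytochalasin D depolymerizes actin and suppresses the
nuclear-shape oscillation).

The speed targets are the published per-interval 3D telomere speeds
(0.12 µm/s in leptotene/zygotene, 0.13 µm/s in pachytene, 0.083 µm/s in
diplotene at 7 s sampling); focus-number layouts follow mouse karyotype
arithmetic (2n = 40 telocentric chromosomes, hence 80 telomeric foci before and
40 after full synapsis).
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

DRUG_MODES = ("none", "dmso", "nocodazole", "cytochalasinD", "both")

STAGE_NAMES = (
    "leptozygotene",
    "bouquet",
    "pachytene",
    "diplotene",
    "sun1_null",
    "sun1_rescue",
)


@dataclass(frozen=True)
class StagePreset:
    """Parameter bundle for one simulated condition.

    Attributes
    ----------
    v_target:
        Expected *measured* per-interval 3D speed (µm/s) at the stage's sampling
        interval; the simulator calibrates its step lengths so that the mean
        ground-truth interval speed matches this value.
    paired_pairs:
        Number of homolog end pairs. In stages up to pachytene paired ends are
        optically merged (co-located); in diplotene they are tethered at a
        distance instead (see d_short_um / d_long_um).
    merged_pairs:
        Whether paired ends are co-located (True) or tethered (False).
    """

    name: str
    n_telomeres: int = 80
    v_target: float = 0.12           # µm/s, measured per-interval speed
    speed_cv: float = 0.35           # CV of the per-interval step length
    omega: float = 0.005             # rad/s rigid nuclear rotation
    kappa: float = 4.0               # heading persistence (von Mises)
    bouquet_cap_halfangle: float | None = None   # rad
    clustered_fraction: float = 0.0
    clustered_v_target: float = 0.0  # µm/s
    paired_pairs: int = 0
    merged_pairs: bool = True
    d_short_um: float | None = None  # short-arm pair separation cap
    d_long_um: float | None = None   # long-arm pair separation cap
    n_internal: int = 0
    deform_amplitude: float = 0.10   # oscillatory mode amplitude (dimensionless)
    deform_period_s: float = 120.0
    static_deform: float = 0.08      # fixed co-rotating asphericity
    n_heterochromatin: int = 10
    drug_mode: str = "none"

    def __post_init__(self):
        if self.v_target < 0 or self.clustered_v_target < 0:
            raise ValueError("speed targets must be >= 0")
        if not 0 <= 2 * self.paired_pairs <= self.n_telomeres:
            raise ValueError("0 <= paired_pairs <= n_telomeres/2 violated")
        if self.d_short_um is not None and self.d_long_um is not None:
            if self.d_short_um > self.d_long_um:
                raise ValueError("short-arm cap must not exceed long-arm cap")
        if self.drug_mode not in DRUG_MODES:
            raise ValueError(f"unknown drug_mode {self.drug_mode!r}; valid: {DRUG_MODES}")
        if self.deform_amplitude < 0 or self.deform_amplitude + self.static_deform >= 0.3:
            raise ValueError("deform amplitudes must satisfy 0 <= a, a + a_static < 0.3")


_BASE: dict[str, StagePreset] = {
    # Pre-synapsis: ~80 distinct telomeric foci, fast motion, rotation on.
    "leptozygotene": StagePreset(
        name="leptozygotene", n_telomeres=80, paired_pairs=0, v_target=0.12,
    ),
    # Bouquet: a subset of telomeres is confined to a cap around the MTOC and
    # slowed; overall rotation is suppressed while the bouquet persists.
    "bouquet": StagePreset(
        name="bouquet", n_telomeres=40, paired_pairs=0, v_target=0.12,
        clustered_fraction=0.25, clustered_v_target=0.04,
        bouquet_cap_halfangle=0.60, omega=0.0,
    ),
    # Full synapsis: 40 merged end pairs -> 40 optical foci, fastest motion.
    "pachytene": StagePreset(
        name="pachytene", n_telomeres=80, paired_pairs=40, v_target=0.13,
    ),
    # Desynapsis: pairs resolve but stay chiasma-tethered; short-arm (centromeric)
    # ends ride pericentromeric heterochromatin, rotation ceases, speed drops.
    "diplotene": StagePreset(
        name="diplotene", n_telomeres=80, paired_pairs=40, merged_pairs=False,
        v_target=0.083, omega=0.0, d_short_um=0.85, d_long_um=4.2,
        n_heterochromatin=20,
    ),
    # LINC-complex null: pairing largely fails (5 merged pairs -> 75 foci, >70),
    # 15 telomeres detach from the envelope, movement machinery is crippled.
    "sun1_null": StagePreset(
        name="sun1_null", n_telomeres=80, paired_pairs=5, v_target=0.05,
        omega=0.0, n_internal=15, deform_amplitude=0.05,
    ),
    # Exogenous SUN1 rescue: pairing partly restored (23 pairs -> 57 foci),
    # near-normal attachment (<= 2 internal telomeres).
    "sun1_rescue": StagePreset(
        name="sun1_rescue", n_telomeres=80, paired_pairs=23, v_target=0.12,
        n_internal=2,
    ),
}


def apply_drug_mode(preset: StagePreset, drug_mode: str) -> StagePreset:
    """Return the preset as modified by a culture drug condition.

    nocodazole abolishes microtubule-dependent motion (telomere steps and
    rotation -> 0) but leaves the actin-driven shape oscillation; cytochalasin D
    suppresses the oscillation amplitude (residual 0.01) but leaves motion and
    rotation; "both" combines the two; "dmso" is the vehicle control.
    """
    if drug_mode not in DRUG_MODES:
        raise ValueError(f"unknown drug_mode {drug_mode!r}; valid: {DRUG_MODES}")
    out = replace(preset, drug_mode=drug_mode)
    if drug_mode in ("nocodazole", "both"):
        out = replace(out, v_target=0.0, clustered_v_target=0.0, omega=0.0)
    if drug_mode in ("cytochalasinD", "both"):
        out = replace(out, deform_amplitude=0.01)
    return out


def make_stage_preset(name: str, drug_mode: str = "none") -> StagePreset:
    """Return the default parameter bundle for a named stage/condition.

    Valid names: leptozygotene, bouquet, pachytene, diplotene, sun1_null,
    sun1_rescue, optionally combined with a drug mode
    (none/dmso/nocodazole/cytochalasinD/both).
    """
    try:
        preset = _BASE[name]
    except KeyError:
        raise ValueError(
            f"unknown stage preset {name!r}; valid presets: {', '.join(STAGE_NAMES)}"
        ) from None
    return apply_drug_mode(preset, drug_mode)


@dataclass(frozen=True)
class SpreadPreset:
    """Parameter bundle for a rendered 2D chromosome spread.

    Count-style presets place all telomeric foci across the flattened nucleus
    (for focus-number quantification); colocalization-style presets place
    `n_peripheral` foci in the nuclear-envelope annulus of a single optical
    section together with microtubule cables, each focus lying on a cable with
    probability `p_on`.
    """

    name: str
    n_telomeres: int = 80
    paired_pairs: int = 0
    n_peripheral: int = 25
    p_on: float | None = None
    n_cables: int = 5
    nucleus_radius_um: float = 8.0
    annulus_um: tuple[float, float] = (6.3, 8.3)
    pixel_size_um: float = 0.1
    image_px: int = 256

    @property
    def n_sites(self) -> int:
        """Distinct focus sites after merging paired ends."""
        return self.n_telomeres - self.paired_pairs


_SPREADS: dict[str, SpreadPreset] = {
    "unpaired": SpreadPreset(name="unpaired", n_telomeres=80, paired_pairs=0),
    "synapsed": SpreadPreset(name="synapsed", n_telomeres=80, paired_pairs=40),
    "sun1_rescue": SpreadPreset(name="sun1_rescue", n_telomeres=80, paired_pairs=23),
    # Colocalization figures: ~25 peripheral foci per optical section,
    # 74% on-cable in WT zygotene vs 45% without SUN1.
    "wt": SpreadPreset(name="wt", n_telomeres=80, paired_pairs=0,
                       n_peripheral=25, p_on=0.74),
    "sun1_null": SpreadPreset(name="sun1_null", n_telomeres=80, paired_pairs=5,
                              n_peripheral=26, p_on=0.45),
}


def make_spread_preset(name: str) -> SpreadPreset:
    """Default spread bundle; names: unpaired, synapsed, sun1_rescue, wt, sun1_null."""
    try:
        return _SPREADS[name]
    except KeyError:
        raise ValueError(
            f"unknown spread preset {name!r}; valid presets: {', '.join(_SPREADS)}"
        ) from None
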