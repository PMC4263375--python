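"""End-to-end experiment drivers tying simulate -> render -> detect -> link ->
measure into reproducible runs, plus a serializable run configuration.

Each driver reproduces one figure-style protocol on synthetic cells:

- :func:`velocity_experiment` — per-stage pooled interval velocities
  (5 telomeres x 10 intervals x 5 cells at 7 s sampling);
- :func:`pair_distance_experiment` — diplotene short-/long-arm homolog pair
  separations over a 3.5-minute window;
- :func:`spread_count_experiment` / :func:`internal_count_experiment` —
  focus-number and internal-telomere quantification;
- :func:`coloc_experiment` — telomere/microtubule-cable colocalization over
  many spreads;
- :func:`shape_experiment` — the XOR nuclear-oscillation statistic per drug
  condition;
- :func:`bouquet_experiment` — clustered vs cluster-free telomere mobility.

Every stochastic step takes an explicit seed; per-cell seeds are derived from
a base seed so whole experiments are reproducible end to end.
"""
from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .detect import (detect_foci_3d, detections_to_array, nucleus_boundary_3d,
                     segment_cables)
from .model import GroundTruth, ImageStack4D
from .motion import (BouquetMetrics, bouquet_metrics, interval_velocities,
                     pair_distance_series, stage_velocity_summary)
from .presets import make_spread_preset, make_stage_preset
from .render import RenderParams, render_spread, render_stack
from .shape import oscillation_summary
from .simulate import simulate_timelapse
from .spread_analysis import (aggregate_coloc, coloc_ratio,
                              count_internal_telomeres, count_trf1_foci)
from .tracking import Track, link_tracks, select_traceable


def derive_seed(base: int, index: int) -> int:
    """Deterministic per-item seed below 2**31."""
    return int((base * 100003 + 7919 * index + 13) % (2 ** 31 - 1))


# --------------------------------------------------------------------------
# shared plumbing

def detect_stack(stack: ImageStack4D, **kw):
    """Per-frame 3D focus detection over a whole stack."""
    return [detect_foci_3d(stack, f, **kw) for f in range(stack.n_frames)]


def nucleus_centers(stack: ImageStack4D) -> np.ndarray:
    """Per-frame 3D centroid of the segmented nucleus (µm, image frame)."""
    return np.array([nucleus_boundary_3d(stack, f).centroid_um()
                     for f in range(stack.n_frames)])


def drift_corrected_positions(dets_by_frame, centers) -> list[np.ndarray]:
    """Detection coordinates re-expressed relative to the nucleus centroid.

    Removes translational drift before linking/measuring, as configured by
    default (the cells are immobilized, but segmentation centroids wander at
    the few-nm level and real acquisitions drift).
    """
    out = []
    for f, dets in enumerate(dets_by_frame):
        out.append(detections_to_array(dets) - centers[f])
    return out


def match_tracks_to_truth(tracks: list[Track], truth: GroundTruth,
                          max_mean_dist_um: float = 0.5) -> dict[int, Track]:
    """Assign tracks to ground-truth telomere ids by mean nucleus-frame distance.

    Tracks must be in the nucleus-centred frame (drift-corrected). Each truth
    id receives at most one track (greedy on mean distance); a track matches
    only when its mean distance over common frames is below the gate.
    """
    cands = []
    for t in tracks:
        pos = t.as_array()
        fr = np.array(t.frames)
        ok = fr < truth.n_frames
        if not ok.any():
            continue
        d = np.linalg.norm(truth.positions_um[fr[ok]][:, :, :]
                           - pos[ok][:, None, :], axis=2)
        mean_d = d.mean(axis=0)
        j = int(np.argmin(mean_d))
        if mean_d[j] <= max_mean_dist_um:
            cands.append((float(mean_d[j]), j, t))
    cands.sort(key=lambda c: c[0])
    out: dict[int, Track] = {}
    used: set[int] = set()
    for _, j, t in cands:
        if j in out or t.track_id in used:
            continue
        out[j] = t
        used.add(t.track_id)
    return out


def assign_track_fragments(tracks: list[Track], truth: GroundTruth,
                           max_dist_um: float = 0.2,
                           min_run: int = 3) -> dict[int, Track]:
    """Strict identity assignment of linked tracks to ground-truth telomeres.

    Each track is scored frame by frame against the nearest ground-truth
    position (after aligning the segmented-centroid frame to the truth frame
    by the per-frame median residual). Runs of >= `min_run` consecutive
    frames that follow one truth id within `max_dist_um` are kept; runs are
    stitched into one track per id. The tight per-frame gate rejects both
    identity switches and merged-pair centroids (which sit at least half the
    pair separation, ~0.28 µm, from either partner).
    """
    # per-frame alignment of the detection frame to the truth frame
    offsets = np.zeros((truth.n_frames, 3))
    deltas: dict[int, list[np.ndarray]] = {}
    for t in tracks:
        for f, p in zip(t.frames, t.positions):
            if f >= truth.n_frames:
                continue
            d = np.linalg.norm(truth.positions_um[f] - p, axis=1)
            j = int(np.argmin(d))
            if d[j] <= 0.8:
                deltas.setdefault(f, []).append(p - truth.positions_um[f][j])
    for f, ds in deltas.items():
        offsets[f] = np.median(np.array(ds), axis=0)

    frags: dict[int, list[tuple[list[int], list[np.ndarray]]]] = {}
    for t in tracks:
        run_f: list[int] = []
        run_p: list[np.ndarray] = []
        run_id = -1

        def flush():
            if len(run_f) >= min_run:
                frags.setdefault(run_id, []).append((list(run_f), list(run_p)))

        for f, p in zip(t.frames, t.positions):
            if f >= truth.n_frames:
                break
            q = p - offsets[f]
            d = np.linalg.norm(truth.positions_um[f] - q, axis=1)
            j = int(np.argmin(d))
            contiguous = bool(run_f) and f == run_f[-1] + 1
            if d[j] <= max_dist_um and (j == run_id or not run_f) and contiguous:
                run_f.append(f)
                run_p.append(p)
            else:
                flush()
                if d[j] <= max_dist_um:
                    run_id, run_f, run_p = j, [f], [p]
                else:
                    run_id, run_f, run_p = -1, [], []
        flush()

    out: dict[int, Track] = {}
    for j, parts in frags.items():
        parts.sort(key=lambda fp: fp[0][0])
        merged = Track(j)
        for fs, ps in parts:
            for f, x in zip(fs, ps):
                if not merged.frames or f > merged.frames[-1]:
                    merged.add(f, x)
        out[j] = merged
    return out


# --------------------------------------------------------------------------
# experiments

@dataclass
class VelocityExperimentResult:
    stage: str
    mean_v_um_s: float
    samples: list[float]
    n_cells: int
    tracks_per_cell: int
    n_intervals: int


def velocity_experiment(stage: str, seed: int = 1, n_cells: int = 5,
                        n_frames: int = 11, dt_s: float = 7.0,
                        tracks_per_cell: int = 5, n_intervals: int = 10,
                        drug_mode: str = "none", drift_correct: bool = True,
                        render_params: RenderParams | None = None
                        ) -> VelocityExperimentResult:
    """Figure-3D-style velocimetry on rendered synthetic cells.

    For each cell: simulate, render, detect foci, link with a gate of
    3 * v_target * dt (floor 1 µm), select tracks with `n_intervals`
    continuous gap-free intervals, keep the `tracks_per_cell` longest-lived,
    and pool all per-interval chord speeds across cells.
    """
    preset = make_stage_preset(stage, drug_mode)
    gate = max(3.0 * preset.v_target * dt_s, 1.0)
    cells = []
    for c in range(n_cells):
        s = derive_seed(seed, c)
        truth = simulate_timelapse(preset, n_frames, dt_s, seed=s)
        stack = render_stack(truth, render_params, seed=s + 1)
        dets = detect_stack(stack)
        pos = (drift_corrected_positions(dets, nucleus_centers(stack))
               if drift_correct
               else [detections_to_array(d) for d in dets])
        tracks = select_traceable(link_tracks(pos, gate), n_intervals)
        tracks.sort(key=lambda t: (-t.n_frames, t.track_id))
        chosen = tracks[:tracks_per_cell]
        cell_samples = []
        for t in chosen:
            cell_samples.extend(interval_velocities(t, dt_s))
        cells.append(cell_samples)
    mean_v, samples = stage_velocity_summary(cells)
    return VelocityExperimentResult(stage=stage, mean_v_um_s=mean_v,
                                    samples=samples, n_cells=n_cells,
                                    tracks_per_cell=tracks_per_cell,
                                    n_intervals=n_intervals)


@dataclass
class PairDistanceResult:
    max_short_um: float
    max_long_um: float
    n_short_pairs: int
    n_long_pairs: int


def pair_distance_experiment(seed: int = 1, n_frames: int = 31,
                             dt_s: float = 7.0,
                             render_params: RenderParams | None = None
                             ) -> PairDistanceResult:
    """Diplotene homolog pair separations through the full pipeline.

    Simulates one diplotene cell for a 3.5-minute window, renders and detects,
    links tracks, matches them to ground-truth telomere ids, and reports the
    maximum 3D separation across frames and pairs for short-arm
    (heterochromatin-associated) and long-arm pairs.
    """
    preset = make_stage_preset("diplotene")
    truth = simulate_timelapse(preset, n_frames, dt_s, seed=seed)
    stack = render_stack(truth, render_params, seed=seed + 1)
    dets = detect_stack(stack)
    pos = drift_corrected_positions(dets, nucleus_centers(stack))
    tracks = link_tracks(pos, max(3.0 * preset.v_target * dt_s, 1.0))
    tracks = [t for t in tracks if t.n_frames >= 3]
    by_id = assign_track_fragments(tracks, truth)
    # only pairs with both partners tracked over overlapping frames are measurable
    measurable = {
        pid: (i, j) for pid, (i, j) in truth.pair_table().items()
        if i in by_id and j in by_id
        and set(by_id[i].frames) & set(by_id[j].frames)
    }
    series = pair_distance_series(by_id, measurable, truth.arm_class)
    mx = {"short": 0.0, "long": 0.0}
    n = {"short": 0, "long": 0}
    for s in series:
        if s.arm_class in mx:
            mx[s.arm_class] = max(mx[s.arm_class], s.max_um)
            n[s.arm_class] += 1
    return PairDistanceResult(max_short_um=mx["short"], max_long_um=mx["long"],
                              n_short_pairs=n["short"], n_long_pairs=n["long"])


def spread_count_experiment(preset_name: str, seed: int = 1) -> int:
    """Render one spread for a pairing-state preset and count TRF1 foci."""
    spread = render_spread(make_spread_preset(preset_name), seed=seed,
                           mode="count")
    return count_trf1_foci(spread)


def internal_count_experiment(stage: str = "sun1_null", seed: int = 1,
                              margin_um: float = 0.8) -> int:
    """Render one cell and count envelope-detached (internal) telomeres."""
    truth = simulate_timelapse(make_stage_preset(stage), 2, 7.0, seed=seed)
    stack = render_stack(truth, seed=seed + 1)
    dets = detect_foci_3d(stack, 0)
    boundary = nucleus_boundary_3d(stack, 0)
    return count_internal_telomeres(dets, boundary, margin_um)


@dataclass
class ColocExperimentResult:
    mean_ratio: float
    sd: float
    pooled_ratio: float
    n_cells: int
    n_foci: int


def coloc_experiment(preset_name: str, n_spreads: int, seed: int = 1,
                     tolerance_um: float = 0.3) -> ColocExperimentResult:
    """Telomere/MT-cable colocalization across simulated spreads.

    Renders `n_spreads` colocalization-style spreads, segments the cable
    network, detects TRF1 foci, and aggregates per-cell on-cable ratios
    (mean with SD across cells, plus the pooled-focus ratio).
    """
    from .detect import detect_foci_2d

    preset = make_spread_preset(preset_name)
    results = []
    n_foci = 0
    for c in range(n_spreads):
        spread = render_spread(preset, seed=derive_seed(seed, c))
        skel = segment_cables(spread)
        dets = detect_foci_2d(spread.channel("TRF1"), spread.pixel_size_um)
        res = coloc_ratio(dets, skel, spread.annulus_mask, tolerance_um)
        results.append(res)
        n_foci += res.n_peripheral
    mean_r, sd, pooled, n_cells = aggregate_coloc(results)
    return ColocExperimentResult(mean_ratio=mean_r, sd=sd, pooled_ratio=pooled,
                                 n_cells=n_cells, n_foci=n_foci)


def shape_experiment(drug_mode: str, seed: int = 1, n_cells: int = 5,
                     n_frames: int = 11, dt_s: float = 30.0,
                     stage: str = "pachytene",
                     render_params: RenderParams | None = None
                     ) -> tuple[float, list[float]]:
    """Mean XOR shape-change ratio for one culture condition.

    Simulates and renders `n_cells` cells at 30 s sampling under the drug
    mode and pools 10 consecutive ratios per cell.
    """
    stacks = []
    for c in range(n_cells):
        s = derive_seed(seed, c)
        truth = simulate_timelapse(make_stage_preset(stage, drug_mode),
                                   n_frames, dt_s, seed=s)
        stacks.append(render_stack(truth, render_params, seed=s + 1))
    return oscillation_summary(stacks, n_intervals=n_frames - 1)


def bouquet_experiment(seed: int = 1, n_frames: int = 11, dt_s: float = 7.0,
                       n_clustered: int = 3, n_free: int = 10,
                       render_params: RenderParams | None = None
                       ) -> BouquetMetrics:
    """Clustered vs cluster-free telomere mobility in a bouquet cell.

    Runs the full pipeline on one bouquet-stage cell, classifies tracks by
    time spent inside the MTOC cap, and compares group velocities using the
    first `n_clustered` / `n_free` qualifying tracks (the tracing protocol of
    the bouquet figure).
    """
    preset = make_stage_preset("bouquet")
    truth = simulate_timelapse(preset, n_frames, dt_s, seed=seed)
    stack = render_stack(truth, render_params, seed=seed + 1)
    dets = detect_stack(stack)
    pos = drift_corrected_positions(dets, nucleus_centers(stack))
    tracks = select_traceable(link_tracks(pos, max(3.0 * preset.v_target * dt_s, 1.0)),
                              n_frames - 1)
    tracks.sort(key=lambda t: t.track_id)
    metrics_all = bouquet_metrics(
        {t.track_id: t.as_array() for t in tracks},
        truth.nucleus.mtoc_dir, dt_s)
    cl = metrics_all.clustered_ids[:n_clustered]
    fr = metrics_all.free_ids[:n_free]
    sub = bouquet_metrics(
        {t.track_id: t.as_array() for t in tracks if t.track_id in cl + fr},
        truth.nucleus.mtoc_dir, dt_s)
    return sub


# --------------------------------------------------------------------------
# run configuration

@dataclass
class RunConfig:
    """Validated, serializable configuration of one end-to-end run."""

    preset: str = "pachytene"
    drug_mode: str = "none"
    seed: int | None = None
    n_cells: int = 1
    n_frames: int = 11
    dt_s: float = 7.0
    tracks_per_cell: int = 5
    n_intervals: int = 10
    gate_um: float | None = None
    drift_correct: bool = True
    out_dir: str = "run_out"
    write_stacks: bool = True

    def validate(self):
        if self.seed is None:
            raise ValueError("config must declare an explicit seed")
        make_stage_preset(self.preset, self.drug_mode)   # name check
        if self.n_frames < 2 or self.n_cells < 1 or self.dt_s <= 0:
            raise ValueError("invalid frame/cell/interval configuration")
        return self

    def to_yaml(self, path):
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data).validate()


def run_experiment(config: RunConfig) -> dict:
    """Execute simulate -> render -> detect -> link -> stats for a config.

    Writes stacks (TIFF + sidecar), ground truth, detections, tracks and a
    summary JSON plus a checksum manifest into `config.out_dir`; returns the
    summary dict. Idempotent for a fixed config. Stage errors carry the cell
    index.
    """
    import json

    from .io import (detections_to_frame, write_ground_truth, write_manifest,
                     write_stack)
    from .tracking import write_tracks_csv

    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    preset = make_stage_preset(config.preset, config.drug_mode)
    gate = config.gate_um or max(3.0 * preset.v_target * config.dt_s, 1.0)

    records: dict[str, int] = {}
    cells = []
    per_cell_means = []
    for c in range(config.n_cells):
        s = derive_seed(config.seed, c)
        try:
            truth = simulate_timelapse(preset, config.n_frames, config.dt_s, seed=s)
            stack = render_stack(truth, seed=s + 1)
            if config.write_stacks:
                write_stack(stack, out / f"cell{c:02d}.tif")
            write_ground_truth(truth, out / f"cell{c:02d}_truth")
            dets = detect_stack(stack)
            detections_to_frame(dets).to_csv(out / f"cell{c:02d}_detections.csv",
                                             index=False)
            pos = (drift_corrected_positions(dets, nucleus_centers(stack))
                   if config.drift_correct
                   else [detections_to_array(d) for d in dets])
            tracks = link_tracks(pos, gate)
            write_tracks_csv(tracks, out / f"cell{c:02d}_tracks.csv")
            chosen = select_traceable(tracks, config.n_intervals)
            chosen.sort(key=lambda t: (-t.n_frames, t.track_id))
            chosen = chosen[: config.tracks_per_cell]
            samples = []
            for t in chosen:
                samples.extend(interval_velocities(t, config.dt_s))
            cells.append(samples)
            if samples:
                per_cell_means.append(float(np.mean([x.v_um_s for x in samples])))
            records[f"cell{c:02d}_detections"] = sum(len(d) for d in dets)
            records[f"cell{c:02d}_tracks"] = len(tracks)
        except Exception as e:
            raise RuntimeError(f"stage failure at cell {c}: {e}") from e

    mean_v, samples = stage_velocity_summary(cells)
    summary = {
        "preset": config.preset, "drug_mode": config.drug_mode,
        "seed": config.seed, "n_cells": config.n_cells,
        "mean_v_um_s": mean_v, "n_samples": len(samples),
        "per_cell_mean_v_um_s": per_cell_means,
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    config.to_yaml(out / "config.yaml")
    write_manifest(out, asdict(config), records)
    return summary
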