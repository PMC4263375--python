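"""File formats: TIFF stacks with JSON sidecars, ground-truth and result tables.

Stacks are written as plain multi-page TIFF in TCZYX page order with a JSON
sidecar (same basename, .json) holding axes, voxel sizes, frame interval,
channel names and the lab-frame origin — everything needed to reconstruct
physical coordinates. Ground truth goes to CSV (one row per telomere per
frame) plus a JSON header (nucleus, preset, seed).
"""
from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .model import GroundTruth, ImageStack4D


def write_stack(stack: ImageStack4D, path) -> Path:
    """Write a stack as TIFF + JSON sidecar; returns the TIFF path."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    t, c, z, y, x = stack.data.shape
    tifffile.imwrite(path, stack.data.reshape(t * c * z, y, x),
                     photometric="minisblack")
    sidecar = {
        "axes": "TCZYX",
        "shape": list(stack.data.shape),
        "channel_names": list(stack.channel_names),
        "voxel_size_um": list(stack.voxel_size_um),
        "frame_interval_s": stack.frame_interval_s,
        "origin_um": np.asarray(stack.origin_um).tolist(),
        "meta": _jsonable(stack.meta),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    return path


def read_stack(path) -> ImageStack4D:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    pages = tifffile.imread(path)
    shape = sidecar["shape"]
    data = np.asarray(pages).reshape(shape)
    return ImageStack4D(
        data=data,
        channel_names=tuple(sidecar["channel_names"]),
        voxel_size_um=tuple(sidecar["voxel_size_um"]),
        frame_interval_s=sidecar["frame_interval_s"],
        origin_um=np.array(sidecar["origin_um"]),
        meta=sidecar.get("meta", {}),
    )


def ground_truth_to_frame(truth: GroundTruth) -> pd.DataFrame:
    T, N, _ = truth.positions_um.shape
    frames = np.repeat(np.arange(T), N)
    ids = np.tile(np.arange(N), T)
    pos = truth.positions_um.reshape(T * N, 3)
    return pd.DataFrame({
        "frame": frames, "id": ids,
        "x_um": pos[:, 0], "y_um": pos[:, 1], "z_um": pos[:, 2],
        "pair_id": np.tile(truth.pair_id, T),
        "arm_class": np.tile(truth.arm_class.astype(str), T),
        "clustered": np.tile(truth.clustered, T),
        "radial_frac": np.tile(truth.radial_frac, T),
    })


def write_ground_truth(truth: GroundTruth, base_path) -> tuple[Path, Path]:
    """CSV of per-frame coordinates + JSON header; returns both paths."""
    base = Path(base_path)
    base.parent.mkdir(parents=True, exist_ok=True)
    csv_path = base.with_suffix(".csv")
    ground_truth_to_frame(truth).to_csv(csv_path, index=False)
    nuc = truth.nucleus
    header = {
        "preset": truth.preset_name,
        "drug_mode": truth.drug_mode,
        "seed": truth.seed,
        "dt_s": truth.dt_s,
        "n_frames": truth.n_frames,
        "nucleus": {
            "radius_um": nuc.radius_um,
            "rotation_axis": nuc.rotation_axis.tolist(),
            "omega_rad_s": nuc.omega,
            "mtoc_dir": nuc.mtoc_dir.tolist(),
            "mtoc_um": truth.mtoc_um.tolist(),
            "deform_amplitude": nuc.deform_amplitude,
            "deform_period_s": nuc.deform_period_s,
            "static_deform": nuc.static_deform,
        },
        "heterochromatin_first_frame_um": truth.heterochromatin_um[0].tolist(),
    }
    json_path = base.with_suffix(".truth.json")
    json_path.write_text(json.dumps(header, indent=1))
    return csv_path, json_path


def detections_to_frame(dets_by_frame) -> pd.DataFrame:
    rows = []
    for dets in dets_by_frame:
        for d in dets:
            rows.append({"frame": d.frame, "x_um": d.x_um, "y_um": d.y_um,
                         "z_um": d.z_um, "intensity": d.intensity,
                         "quality": d.quality})
    return pd.DataFrame(rows, columns=["frame", "x_um", "y_um", "z_um",
                                       "intensity", "quality"])


def sha256_of(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(out_dir, config_dict, records: dict[str, int]) -> Path:
    """List every output file with a checksum plus per-stage record counts."""
    out_dir = Path(out_dir)
    files = sorted(p for p in out_dir.rglob("*")
                   if p.is_file() and p.name != "manifest.json")
    manifest = {
        "config": _jsonable(config_dict),
        "config_hash": hashlib.sha256(
            json.dumps(_jsonable(config_dict), sort_keys=True).encode()
        ).hexdigest(),
        "records": records,
        "files": {str(p.relative_to(out_dir)): sha256_of(p) for p in files},
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return path


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj
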