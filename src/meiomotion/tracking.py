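"""Frame-to-frame linking of detections into trajectories.

Linking is globally optimal per frame pair: a Hungarian assignment minimizing
total squared displacement among candidate pairs inside a distance gate, which
removes any dependence on detection input order. Tracks may bridge a single
missing frame (gap closing with a doubled gate) — at 7 s sampling a longer
memory is not warranted. Tracks shorter than `min_length` frames are dropped
from downstream statistics by default.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .detect import FocusDetection, detections_to_array


@dataclass
class Track:
    """One linked trajectory: strictly increasing frames, positions in µm."""

    track_id: int
    frames: list[int] = field(default_factory=list)
    positions: list[np.ndarray] = field(default_factory=list)
    gap_frames: set[int] = field(default_factory=set)

    def add(self, frame: int, pos: np.ndarray, gap: bool = False):
        if self.frames and frame <= self.frames[-1]:
            raise ValueError("frames must be strictly increasing")
        self.frames.append(frame)
        self.positions.append(np.asarray(pos, dtype=float))
        if gap:
            self.gap_frames.add(frame)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def as_array(self) -> np.ndarray:
        return np.array(self.positions)

    def window(self, start: int, n_frames: int) -> "Track":
        """Sub-track covering frames [start, start + n_frames)."""
        idx = [i for i, f in enumerate(self.frames)
               if start <= f < start + n_frames]
        t = Track(self.track_id)
        for i in idx:
            t.add(self.frames[i], self.positions[i],
                  gap=self.frames[i] in self.gap_frames)
        return t


def _as_position_list(detections_by_frame) -> list[np.ndarray]:
    out = []
    for dets in detections_by_frame:
        if isinstance(dets, np.ndarray):
            out.append(dets.reshape(-1, 3).astype(float))
        else:
            out.append(detections_to_array(list(dets)))
    return out


def link_tracks(detections_by_frame, gate_um: float) -> list[Track]:
    """Link per-frame detections into tracks.

    Parameters
    ----------
    detections_by_frame:
        Sequence over frames; each element either a list of FocusDetection or
        an (n, 3) array of (x, y, z) µm positions. Empty input yields no tracks.
    gate_um:
        Maximum frame-to-frame displacement considered (a sensible default is
        3 * v_target * dt for the analyzed stage). A track may additionally
        bridge one missing frame within twice the gate; the bridged frame is
        flagged as a gap.
    """
    if gate_um <= 0:
        raise ValueError("gate must be positive")
    frames = _as_position_list(detections_by_frame)
    tracks: list[Track] = []
    open_tracks: list[Track] = []
    next_id = 0

    for f, pts in enumerate(frames):
        matched_det: set[int] = set()
        # primary pass: tracks ending at f-1 with gate; secondary: f-2, 2x gate
        for lag, gate in ((1, gate_um), (2, 2 * gate_um)):
            cand = [t for t in open_tracks if t.frames[-1] == f - lag]
            if not cand or not len(pts):
                continue
            free = [j for j in range(len(pts)) if j not in matched_det]
            if not free:
                continue
            last = np.array([t.positions[-1] for t in cand])
            cost = ((last[:, None, :] - pts[free][None, :, :]) ** 2).sum(-1)
            big = 4.0 * max(gate, 1.0) ** 2 * (cost.shape[0] + cost.shape[1])
            blocked = cost > gate * gate
            cost_h = np.where(blocked, big, cost)
            rows, cols = linear_sum_assignment(cost_h)
            for r, c in sorted(zip(rows, cols),
                               key=lambda rc: (cost_h[rc[0], rc[1]],
                                               cand[rc[0]].track_id)):
                if blocked[r, c]:
                    continue
                j = free[c]
                if lag == 2:   # gap closing: mark the bridged (missing) frame
                    cand[r].gap_frames.add(f - 1)
                cand[r].add(f, pts[j])
                matched_det.add(j)

        for j in range(len(pts)):
            if j not in matched_det:
                t = Track(next_id)
                next_id += 1
                t.add(f, pts[j])
                open_tracks.append(t)
        # retire tracks that have been silent for more than one frame
        still_open, retired = [], []
        for t in open_tracks:
            (still_open if t.frames[-1] >= f - 1 else retired).append(t)
        open_tracks = still_open
        tracks.extend(retired)
    tracks.extend(open_tracks)
    tracks.sort(key=lambda t: t.track_id)
    return tracks


def select_traceable(tracks: list[Track], n_required_intervals: int = 10,
                     min_length: int = 3) -> list[Track]:
    """Tracks with >= n_required consecutive gap-free intervals, trimmed.

    Mirrors the tracing protocol of the live-imaging figures (10 continuous
    7-s intervals per telomere): a returned track is the *first* window of
    n_required_intervals + 1 consecutive frames with no bridged gap inside.
    """
    out = []
    need = n_required_intervals + 1
    for t in tracks:
        if t.n_frames < max(need, min_length):
            continue
        fr = t.frames
        run_start = 0
        found = None
        for i in range(1, t.n_frames):
            contiguous = fr[i] == fr[i - 1] + 1 and fr[i] not in t.gap_frames
            if not contiguous:
                run_start = i
            if i - run_start + 1 >= need:
                found = fr[run_start]
                break
        if found is not None:
            out.append(t.window(found, need))
    return out


# --------------------------------------------------------------------------
# round-trip CSV I/O

def tracks_to_frame(tracks: list[Track]) -> pd.DataFrame:
    rows = []
    for t in tracks:
        for f, p in zip(t.frames, t.positions):
            rows.append({"track_id": t.track_id, "frame": f,
                         "x_um": p[0], "y_um": p[1], "z_um": p[2],
                         "gap": f in t.gap_frames})
    return pd.DataFrame(rows, columns=["track_id", "frame", "x_um", "y_um",
                                       "z_um", "gap"])


def write_tracks_csv(tracks: list[Track], path):
    tracks_to_frame(tracks).to_csv(path, index=False)


def read_tracks_csv(path) -> list[Track]:
    df = pd.read_csv(path)
    out = []
    for tid, grp in df.groupby("track_id", sort=True):
        t = Track(int(tid))
        for _, row in grp.sort_values("frame").iterrows():
            t.add(int(row.frame), np.array([row.x_um, row.y_um, row.z_um]),
                  gap=bool(row.get("gap", False)))
        out.append(t)
    return out
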