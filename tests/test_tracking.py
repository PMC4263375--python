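"""Linker: optimality, invariances, traceability selection, round trips."""
import itertools

import numpy as np
import pytest

from meiomotion.tracking import (Track, link_tracks, read_tracks_csv,
                                 select_traceable, write_tracks_csv)


def test_stationary_detection_single_track():
    frames = [np.array([[1.0, 2.0, 3.0]])] * 10
    tracks = link_tracks(frames, gate_um=1.0)
    assert len(tracks) == 1
    assert tracks[0].n_frames == 10


def test_empty_input_empty_output():
    assert link_tracks([], 1.0) == []
    assert link_tracks([np.zeros((0, 3))] * 3, 1.0) == []


def test_gate_must_be_positive():
    with pytest.raises(ValueError):
        link_tracks([np.zeros((1, 3))], 0.0)


def test_two_by_two_assignment_matches_brute_force():
    """Hungarian minimizes total squared displacement: check against explicit
    enumeration of both 2x2 assignments for configurations that tempt a swap."""
    rng = np.random.default_rng(5)
    for _ in range(25):
        a = rng.uniform(0, 4, size=(2, 3))
        b = rng.uniform(0, 4, size=(2, 3))
        tracks = link_tracks([a, b], gate_um=10.0)
        got = {}
        for t in tracks:
            if t.n_frames == 2:
                i = int(np.argmin(np.linalg.norm(a - t.positions[0], axis=1)))
                j = int(np.argmin(np.linalg.norm(b - t.positions[1], axis=1)))
                got[i] = j
        best, best_cost = None, np.inf
        for perm in itertools.permutations(range(2)):
            cost = sum(np.sum((a[i] - b[perm[i]]) ** 2) for i in range(2))
            if cost < best_cost:
                best, best_cost = {i: perm[i] for i in range(2)}, cost
        assert got == best


def test_linking_permutation_invariant():
    rng = np.random.default_rng(9)
    frames = [rng.uniform(0, 10, size=(8, 3)) for _ in range(5)]
    tracks_a = link_tracks(frames, 3.0)
    shuffled = [f[rng.permutation(len(f))] for f in frames]
    tracks_b = link_tracks(shuffled, 3.0)
    # identical sets of (frame, position) sequences regardless of input order
    sig_a = sorted(tuple(map(tuple, np.round(t.as_array(), 9))) for t in tracks_a)
    sig_b = sorted(tuple(map(tuple, np.round(t.as_array(), 9))) for t in tracks_b)
    assert sig_a == sig_b


def test_noise_free_identity_when_steps_small():
    """Assignment is exact when inter-telomere spacing exceeds 2x the max step."""
    rng = np.random.default_rng(3)
    base = rng.uniform(0, 30, size=(12, 3))
    d = np.linalg.norm(base[:, None] - base[None, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    step = 0.4 * d.min() / 2
    frames = [base + rng.uniform(-step, step, size=base.shape) * (f > 0)
              for f in range(6)]
    tracks = link_tracks(frames, gate_um=d.min() / 2)
    assert len(tracks) == 12
    for t in tracks:
        i = int(np.argmin(np.linalg.norm(base - t.positions[0], axis=1)))
        for p in t.positions:
            assert np.linalg.norm(p - base[i]) <= 2 * step + 1e-9


def test_gap_closing_bridges_one_missing_frame():
    p = np.array([[5.0, 5.0, 5.0]])
    frames = [p, np.zeros((0, 3)), p + 0.1]
    tracks = link_tracks(frames, gate_um=1.0)
    assert len(tracks) == 1
    assert tracks[0].frames == [0, 2]
    assert tracks[0].gap_frames == {1}


def test_select_traceable_rules():
    t = Track(0)
    for f in range(11):
        t.add(f, np.array([0.0, 0, 0]))
    kept = select_traceable([t], 10)
    assert len(kept) == 1 and kept[0].n_frames == 11

    gappy = Track(1)
    for f in range(12):
        gappy.add(f, np.zeros(3), gap=(f == 6))   # bridged gap mid-window
    assert select_traceable([gappy], 10) == []

    assert select_traceable([], 10) == []


def test_select_traceable_trims_to_first_window():
    t = Track(0)
    for f in range(15):
        t.add(f, np.array([float(f), 0, 0]))
    kept = select_traceable([t], 10)
    assert kept[0].frames == list(range(11))


def test_tracks_csv_round_trip(tmp_path):
    rng = np.random.default_rng(1)
    frames = [rng.uniform(0, 5, size=(3, 3)) for _ in range(4)]
    tracks = link_tracks(frames, 10.0)
    path = tmp_path / "tracks.csv"
    write_tracks_csv(tracks, path)
    back = read_tracks_csv(path)
    assert len(back) == len(tracks)
    for a, b in zip(tracks, back):
        assert a.frames == b.frames
        assert np.allclose(a.as_array(), b.as_array())
        assert a.gap_frames == b.gap_frames
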