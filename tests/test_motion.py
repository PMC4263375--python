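"""Motion statistics: velocities, rotation, pairs, bouquet, MTOC, Welch test."""
import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from meiomotion.motion import (bouquet_metrics, estimate_rotation,
                               interval_velocities, mtoc_stability,
                               pair_distance_series, rotation_series,
                               stage_velocity_summary, unidirectionality,
                               welch_t_test)
from meiomotion.tracking import Track


def _track(positions, start=0):
    t = Track(0)
    for i, p in enumerate(positions):
        t.add(start + i, np.asarray(p, dtype=float))
    return t


def test_interval_velocity_arithmetic():
    # displacement (0.7, 0, 0) µm over 7 s -> 0.1 µm/s
    v = interval_velocities(_track([[0, 0, 0], [0.7, 0, 0]]), 7.0)
    assert len(v) == 1 and v[0].v_um_s == pytest.approx(0.1)


def test_stationary_track_zero_velocity():
    v = interval_velocities(_track([[1, 1, 1]] * 5), 7.0)
    assert all(s.v_um_s == 0.0 for s in v)


def test_velocity_window_validation():
    with pytest.raises(ValueError):
        interval_velocities(_track([[0, 0, 0]]), 7.0)
    with pytest.raises(ValueError):
        interval_velocities(_track([[0, 0, 0], [1, 0, 0]]), 0.0)
    gappy = Track(0)
    gappy.add(0, np.zeros(3))
    gappy.add(1, np.zeros(3), gap=True)
    with pytest.raises(ValueError, match="gap"):
        interval_velocities(gappy, 7.0)


def test_stage_velocity_summary_pools():
    cells = [interval_velocities(_track([[0, 0, 0], [0.7, 0, 0]]), 7.0),
             interval_velocities(_track([[0, 0, 0], [1.4, 0, 0]]), 7.0)]
    mean, samples = stage_velocity_summary(cells)
    assert mean == pytest.approx(0.15)
    assert len(samples) == 2
    with pytest.raises(ValueError):
        stage_velocity_summary([[]])


def test_rotation_identity_is_zero():
    pts = np.random.default_rng(0).normal(size=(6, 3))
    e = estimate_rotation(pts, pts, np.zeros(3))
    assert e.angle_rad == pytest.approx(0.0, abs=1e-9)


def test_rotation_construct_and_recover_exact():
    """Known rotation recovered to numerical precision on exact input."""
    rng = np.random.default_rng(2)
    pts = rng.normal(size=(10, 3)) * 3
    true = Rotation.from_rotvec(0.15 * np.array([0.0, 0.0, 1.0]))
    e = estimate_rotation(pts, true.apply(pts), np.zeros(3))
    assert e.angle_rad == pytest.approx(0.15, abs=1e-9)
    assert np.allclose(e.axis, [0, 0, 1], atol=1e-9)


def test_rotation_arbitrary_axis_and_center():
    rng = np.random.default_rng(4)
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    center = np.array([3.0, -2.0, 1.0])
    pts = rng.normal(size=(8, 3)) + center
    rot = Rotation.from_rotvec(0.4 * axis)
    moved = rot.apply(pts - center) + center
    e = estimate_rotation(pts, moved, center)
    assert e.angle_rad == pytest.approx(0.4, abs=1e-9)
    assert np.dot(e.axis, axis) == pytest.approx(1.0, abs=1e-9)


def test_rotation_degenerate_inputs_error():
    with pytest.raises(ValueError):
        estimate_rotation(np.zeros((2, 3)), np.zeros((2, 3)), np.zeros(3))
    line = np.outer(np.arange(5.0), [1.0, 0, 0])
    with pytest.raises(ValueError, match="collinear"):
        estimate_rotation(line, line, np.zeros(3))


def test_unidirectionality_extremes():
    rng = np.random.default_rng(6)
    pts = rng.normal(size=(8, 3)) * 4
    rot = Rotation.from_rotvec(0.1 * np.array([0, 0, 1.0]))
    hetero = np.array([rot.apply(pts, inverse=False) for _ in range(6)])
    for f in range(6):
        hetero[f] = Rotation.from_rotvec(0.1 * f * np.array([0, 0, 1.0])).apply(pts)
    ests = rotation_series(hetero)
    assert unidirectionality(ests) == pytest.approx(1.0, abs=1e-9)
    # alternating back-and-forth rotation -> U ~ 0
    wobble = np.array([Rotation.from_rotvec(0.1 * (f % 2) * np.array([0, 0, 1.0])).apply(pts)
                       for f in range(7)])
    assert unidirectionality(rotation_series(wobble)) < 0.25


def test_pair_distance_series_basics():
    a = _track([[0, 0, 0], [1, 0, 0], [2, 0, 0]])
    b = _track([[0, 0, 0], [1, 0, 0], [2, 0, 0]])
    series = pair_distance_series({0: a, 1: b}, {0: (0, 1)})
    assert np.allclose(series[0].distance_um, 0.0)    # coincident pair

    c = _track([[0, 0, 0]], start=7)                  # no common frames
    with pytest.raises(ValueError, match="common"):
        pair_distance_series({0: a, 1: c}, {0: (0, 1)})


def test_bouquet_classification_and_fraction():
    rng = np.random.default_rng(8)
    mtoc = np.array([0.0, 0.0, 1.0])
    # all telomeres parked inside the cap -> fraction 1
    inside = {i: np.tile([0.1, 0.0, 5.0], (5, 1)) for i in range(4)}
    m = bouquet_metrics(inside, mtoc, 7.0)
    assert m.clustered_fraction == 1.0
    assert m.free_mean_v is None and m.clustered_mean_v == 0.0

    # uniformly distributed directions -> fraction ~ cap solid-angle fraction
    n = 4000
    dirs = rng.normal(size=(n, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    pos = {i: np.tile(5 * dirs[i], (3, 1)) for i in range(n)}
    m2 = bouquet_metrics(pos, mtoc, 7.0, cap_halfangle=np.deg2rad(40))
    expected = (1 - np.cos(np.deg2rad(40))) / 2
    assert m2.clustered_fraction == pytest.approx(expected, abs=0.02)


def test_bouquet_cap_validation():
    with pytest.raises(ValueError):
        bouquet_metrics({}, np.array([0, 0, 1.0]), 7.0, cap_halfangle=2.0)


def test_mtoc_stability():
    with pytest.raises(ValueError):
        mtoc_stability(np.zeros((0, 3)))
    jitter = np.random.default_rng(1).normal(scale=0.05, size=(10, 3))
    s = mtoc_stability(jitter + [5, 5, 5])
    assert s.max_displacement_um < 0.3
    # misuse contrast: rotating the MTOC with the frame gives R * total angle
    R, omega, dt = 5.0, 0.005, 30.0
    angles = omega * dt * np.arange(10)
    orbit = np.stack([R * np.cos(angles), R * np.sin(angles),
                      np.zeros(10)], axis=1)
    s2 = mtoc_stability(orbit)
    assert s2.path_length_um == pytest.approx(R * angles[-1], rel=0.01)
    assert s2.max_displacement_um > 10 * s.max_displacement_um


def test_welch_identical_samples():
    t, df, p = welch_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert t == 0.0 and p == pytest.approx(1.0)


def test_welch_matches_hand_formula():
    """Cross-check against the explicit Welch statistic and Satterthwaite df."""
    rng = np.random.default_rng(11)
    a = rng.normal(0.13, 0.05, size=40)
    b = rng.normal(0.10, 0.04, size=25)
    t, df, p = welch_t_test(a, b)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    t_hand = (a.mean() - b.mean()) / np.sqrt(va + vb)
    df_hand = (va + vb) ** 2 / (va ** 2 / (len(a) - 1) + vb ** 2 / (len(b) - 1))
    assert t == pytest.approx(t_hand, rel=1e-12)
    assert df == pytest.approx(df_hand, rel=1e-12)
    from scipy import stats

    assert p == pytest.approx(2 * stats.t.sf(abs(t_hand), df_hand), rel=1e-12)


def test_welch_stage_difference_significant():
    """Pachytene- vs diplotene-like samples separate at the published
    significance threshold (two-tailed p < 0.0005)."""
    rng = np.random.default_rng(12)
    a = rng.normal(0.13, 0.05, size=250)
    b = rng.normal(0.083, 0.04, size=250)
    _, _, p = welch_t_test(a, b)
    assert p < 0.0005


def test_welch_validation():
    with pytest.raises(ValueError):
        welch_t_test([1.0], [1.0, 2.0])
    with pytest.raises(ValueError):
        welch_t_test([1.0, np.nan], [1.0, 2.0])
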