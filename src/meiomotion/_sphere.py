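"""Small spherical-geometry helpers shared by the simulator and the statistics.

All vectors are float64 numpy arrays; unit directions live on S^2. Angles are in
radians, distances in micrometres unless stated otherwise.
"""
from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation


def unit(v: np.ndarray, axis: int = -1) -> np.ndarray:
    """Normalize vectors along `axis`; zero vectors raise."""
    n = np.linalg.norm(v, axis=axis, keepdims=True)
    if np.any(n == 0):
        raise ValueError("cannot normalize zero vector")
    return v / n


def random_unit_vectors(rng: np.random.Generator, n: int) -> np.ndarray:
    """n directions uniform on the sphere (Gaussian projection)."""
    return unit(rng.normal(size=(n, 3)))


def angular_distance(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Angle between unit vectors, broadcast over leading axes."""
    d = np.sum(u * v, axis=-1)
    return np.arccos(np.clip(d, -1.0, 1.0))


def tangent_frame(u: np.ndarray, rng: np.random.Generator | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Two orthonormal tangent vectors at each unit direction u (shape (..., 3)).

    The frame is deterministic (built from the least-aligned coordinate axis);
    `rng` is accepted for callers that want a randomly rotated frame.
    """
    u = np.asarray(u, dtype=float)
    ref = np.zeros_like(u)
    idx = np.argmin(np.abs(u), axis=-1)
    np.put_along_axis(ref, idx[..., None], 1.0, axis=-1)
    t1 = unit(np.cross(u, ref))
    t2 = np.cross(u, t1)
    if rng is not None:
        phi = rng.uniform(0, 2 * np.pi, size=u.shape[:-1] + (1,))
        t1, t2 = (np.cos(phi) * t1 + np.sin(phi) * t2,
                  -np.sin(phi) * t1 + np.cos(phi) * t2)
    return t1, t2


def random_tangents(rng: np.random.Generator, u: np.ndarray) -> np.ndarray:
    """Uniformly random unit tangent at each direction u."""
    t1, t2 = tangent_frame(u)
    phi = rng.uniform(0, 2 * np.pi, size=u.shape[:-1] + (1,))
    return np.cos(phi) * t1 + np.sin(phi) * t2


def geodesic_step(u: np.ndarray, heading: np.ndarray, arc_angle: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Advance unit directions along great circles.

    Parameters
    ----------
    u : (..., 3) unit directions.
    heading : (..., 3) unit tangents at u.
    arc_angle : (...,) arc length in radians (arc length on sphere of radius R
        divided by R).

    Returns the new directions and the parallel-transported headings (the
    tangent of the same great circle at the new point).
    """
    a = np.asarray(arc_angle)[..., None]
    u_new = u * np.cos(a) + heading * np.sin(a)
    h_new = -u * np.sin(a) + heading * np.cos(a)
    return u_new, h_new


def rotate_about(points: np.ndarray, axis: np.ndarray, angle: float,
                 center: np.ndarray | None = None) -> np.ndarray:
    """Rigidly rotate points (or directions) about `axis` through `center`."""
    rot = Rotation.from_rotvec(np.asarray(axis, dtype=float) * float(angle))
    p = np.asarray(points, dtype=float)
    if center is None:
        return rot.apply(p.reshape(-1, 3)).reshape(p.shape)
    c = np.asarray(center, dtype=float)
    return rot.apply((p - c).reshape(-1, 3)).reshape(p.shape) + c


def chord_from_arc(arc_um: np.ndarray, radius_um: float) -> np.ndarray:
    """Chord displacement corresponding to a great-circle arc on a sphere.

    chord = 2 R sin(L / 2R); for L << R this approaches L.
    """
    return 2.0 * radius_um * np.sin(np.asarray(arc_um) / (2.0 * radius_um))


def slerp_toward(u: np.ndarray, target: np.ndarray, angle: np.ndarray) -> np.ndarray:
    """Move unit directions u toward `target` by `angle` along the great circle.

    If the remaining angle is smaller than `angle`, lands on the target.
    """
    full = angular_distance(u, target)
    a = np.minimum(np.asarray(angle), full)
    with np.errstate(invalid="ignore", divide="ignore"):
        e = u - target * np.sum(u * target, axis=-1, keepdims=True)
        norm = np.linalg.norm(e, axis=-1, keepdims=True)
        e = np.where(norm > 1e-12, e / np.where(norm == 0, 1, norm), e)
    new_ang = (full - a)[..., None]
    out = target * np.cos(new_ang) + e * np.sin(new_ang)
    # degenerate (antipodal / coincident) directions: leave unchanged
    bad = (norm[..., 0] <= 1e-12)
    if np.any(bad):
        out = np.where(bad[..., None], u, out)
    return unit(out)


def von_mises_angles(rng: np.random.Generator, kappa: float, size) -> np.ndarray:
    """Turning angles in (-pi, pi] with von Mises concentration kappa about 0."""
    if kappa <= 0:
        return rng.uniform(-np.pi, np.pi, size=size)
    return rng.vonmises(0.0, kappa, size=size)
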