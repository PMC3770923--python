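"""Small 3-D geometry helpers: internal-coordinate atom placement and rigid
transforms. All lengths in Angstrom, angles in degrees at the API surface."""

from __future__ import annotations

import numpy as np


def unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise ValueError("cannot normalise a zero vector")
    return v / n


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """Place atom D given reference atoms a-b-c (NeRF construction).

    D is bonded to ``c`` at distance ``bond``; the angle b-c-D is
    ``angle_deg`` and the dihedral a-b-c-D is ``dihedral_deg``.
    """
    theta = np.radians(angle_deg)
    phi = np.radians(dihedral_deg)
    bc = unit(c - b)
    ab = b - a
    n = np.cross(ab, bc)
    if np.linalg.norm(n) < 1e-10:
        # colinear references: pick any perpendicular, deterministically
        trial = np.array([1.0, 0.0, 0.0])
        if abs(np.dot(trial, bc)) > 0.9:
            trial = np.array([0.0, 1.0, 0.0])
        n = np.cross(trial, bc)
    n = unit(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * np.cos(theta),
        bond * np.sin(theta) * np.cos(phi),
        bond * np.sin(theta) * np.sin(phi),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle p0-p1-p2-p3 in degrees."""
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1u = unit(b1)
    v = b0 - np.dot(b0, b1u) * b1u
    w = b2 - np.dot(b2, b1u) * b1u
    x = np.dot(v, w)
    y = np.dot(np.cross(b1u, v), w)
    return float(np.degrees(np.arctan2(y, x)))


def rotation_about_axis(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotation matrix about a (unit) axis through the origin (Rodrigues)."""
    k = unit(np.asarray(axis, dtype=float))
    t = np.radians(angle_deg)
    K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + np.sin(t) * K + (1 - np.cos(t)) * (K @ K)


def rotation_between(v_from: np.ndarray, v_to: np.ndarray) -> np.ndarray:
    """Minimal rotation taking direction v_from onto v_to (deterministic)."""
    a = unit(np.asarray(v_from, dtype=float))
    b = unit(np.asarray(v_to, dtype=float))
    c = float(np.dot(a, b))
    if c > 1 - 1e-12:
        return np.eye(3)
    if c < -1 + 1e-12:
        # 180 degrees: rotate about any axis perpendicular to a
        trial = np.array([1.0, 0.0, 0.0])
        if abs(np.dot(trial, a)) > 0.9:
            trial = np.array([0.0, 1.0, 0.0])
        axis = unit(np.cross(a, trial))
        return rotation_about_axis(axis, 180.0)
    axis = np.cross(a, b)
    s = np.linalg.norm(axis)
    K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + K + K @ K * ((1 - c) / (s * s))


def angular_shift(predicted_deg: float, reference_deg: float) -> float:
    """Minimal circular difference between two angles, in [0, 180] degrees."""
    d = abs((float(predicted_deg) - float(reference_deg)) % 360.0)
    return min(d, 360.0 - d)
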