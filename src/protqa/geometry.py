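"""Small vector-geometry helpers: dihedrals, angles, internal-coordinate
atom placement (NeRF)."""

from __future__ import annotations

import numpy as np


def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle in degrees for four points."""
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    return float(np.degrees(np.arctan2(y, x)))


def angle(p0, p1, p2) -> float:
    """Bond angle at p1 in degrees."""
    p0, p1, p2 = (np.asarray(p, dtype=float) for p in (p0, p1, p2))
    a = p0 - p1
    b = p2 - p1
    cosang = np.dot(a, b) / (np.linalg.norm(a) * np.linalg.norm(b))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def place_atom(a, b, c, bond: float, theta: float, chi: float) -> np.ndarray:
    """Place atom x with |x-c| = bond, angle(b,c,x) = theta and dihedral
    (a,b,c,x) = chi (degrees). Standard NeRF construction."""
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    theta = np.radians(theta)
    chi = np.radians(chi)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array(
        [
            -bond * np.cos(theta),
            bond * np.sin(theta) * np.cos(chi),
            bond * np.sin(theta) * np.sin(chi),
        ]
    )
    return c + d[0] * bc + d[1] * m + d[2] * n


def rotation_matrix(axis, theta_deg: float) -> np.ndarray:
    """Rotation matrix about an arbitrary axis (Rodrigues)."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    t = np.radians(theta_deg)
    k = np.array(
        [
            [0, -axis[2], axis[1]],
            [axis[2], 0, -axis[0]],
            [-axis[1], axis[0], 0],
        ]
    )
    return np.eye(3) + np.sin(t) * k + (1 - np.cos(t)) * (k @ k)
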