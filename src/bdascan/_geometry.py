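"""Small internal-coordinate geometry helpers shared by fixtures and boronchem."""

from __future__ import annotations

import numpy as np


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle_deg: float, dihedral_deg: float
               ) -> np.ndarray:
    """Place atom D bonded to C given bond length C–D, angle B–C–D and
    dihedral A–B–C–D (natural extension reference frame)."""
    angle = np.deg2rad(angle_deg)
    dihedral = np.deg2rad(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    norm = np.linalg.norm(n)
    if norm < 1e-10:
        # collinear reference: pick any perpendicular
        n = np.cross(bc, [1.0, 0.0, 0.0])
        if np.linalg.norm(n) < 1e-10:
            n = np.cross(bc, [0.0, 1.0, 0.0])
        norm = np.linalg.norm(n)
    n /= norm
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * np.cos(angle),
        bond * np.sin(angle) * np.cos(dihedral),
        bond * np.sin(angle) * np.sin(dihedral),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def dihedral_angle(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray,
                   p3: np.ndarray) -> float:
    """Signed dihedral p0-p1-p2-p3 in degrees."""
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1 = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    return float(np.degrees(np.arctan2(y, x)))


def angle_between(v1: np.ndarray, v2: np.ndarray) -> float:
    """Angle between two 3-vectors in degrees, in [0, 180]."""
    n1 = np.linalg.norm(v1)
    n2 = np.linalg.norm(v2)
    if n1 < 1e-12 or n2 < 1e-12:
        raise ValueError("zero-length vector in angle computation")
    cosang = np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))
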