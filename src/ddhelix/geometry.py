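"""Low-level 3-D geometry: torsions, internal-coordinate atom placement.

All angles are in degrees at the API surface; coordinates in Angstrom.
"""
from __future__ import annotations

import numpy as np

__all__ = ["angle_deg", "dihedral_deg", "place_atom", "rotation_about_axis"]


def angle_deg(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle a-b-c at vertex b."""
    u = a - b
    v = c - b
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def dihedral_deg(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Signed torsion of the chain p0-p1-p2-p3 about the p1->p2 axis, IUPAC sign."""
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1 = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    return float(np.degrees(np.arctan2(y, x)))


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle: float, torsion: float) -> np.ndarray:
    """Place a new atom bonded to ``c`` from internal coordinates (NeRF).

    ``bond`` is the new-c distance, ``angle`` the new-c-b angle and
    ``torsion`` the dihedral a-b-c-new, both in degrees.  The convention
    matches :func:`dihedral_deg`: ``dihedral_deg(a, b, c, new) == torsion``.
    """
    ang = np.radians(angle)
    tor = np.radians(torsion)
    # local displacement in the frame anchored at c
    d = np.array([
        -bond * np.cos(ang),
        bond * np.sin(ang) * np.cos(tor),
        bond * np.sin(ang) * np.sin(tor),
    ])
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    frame = np.column_stack([bc, m, n])
    return c + frame @ d


def rotation_about_axis(axis: np.ndarray, angle_deg_: float) -> np.ndarray:
    """Rotation matrix for a right-handed rotation about ``axis`` (unit not required)."""
    u = np.asarray(axis, dtype=float)
    u = u / np.linalg.norm(u)
    t = np.radians(angle_deg_)
    c, s = np.cos(t), np.sin(t)
    ux, uy, uz = u
    K = np.array([[0.0, -uz, uy], [uz, 0.0, -ux], [-uy, ux, 0.0]])
    return c * np.eye(3) + s * K + (1.0 - c) * np.outer(u, u)
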