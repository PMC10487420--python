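"""Low-level vector geometry: dihedrals, internal-coordinate atom placement, rotations.

All angles at this interface are in degrees; coordinates in Angstroms.
The dihedral sign convention is the one shared by gemmi, Biopython and
MDAnalysis (a right-handed rotation of the far bond viewed along the central
bond is positive), which yields the familiar negative phi values for
right-handed helices.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = [
    "wrap_angle",
    "dihedral",
    "dihedral_many",
    "angle_between",
    "place_atom",
    "rotation_about_axis",
    "random_rotation",
]


def wrap_angle(theta):
    """Wrap an angle (degrees) into [-180, 180). Works on scalars and arrays."""
    return (np.asarray(theta) + 180.0) % 360.0 - 180.0


def angle_between(a, b, c) -> float:
    """Bond angle a-b-c in degrees."""
    u = np.asarray(a, dtype=float) - b
    v = np.asarray(c, dtype=float) - b
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return math.degrees(math.acos(max(-1.0, min(1.0, cosang))))


def dihedral(p0, p1, p2, p3) -> float:
    """Torsion angle p0-p1-p2-p3 in degrees, in [-180, 180)."""
    res = dihedral_many(
        np.asarray(p0, dtype=float)[None, :],
        np.asarray(p1, dtype=float)[None, :],
        np.asarray(p2, dtype=float)[None, :],
        np.asarray(p3, dtype=float)[None, :],
    )
    return float(res[0])


def dihedral_many(p0, p1, p2, p3) -> np.ndarray:
    """Vectorized torsion angles for (N, 3) stacks of points, degrees in [-180, 180)."""
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1n = b1 / np.linalg.norm(b1, axis=-1, keepdims=True)
    v = b0 - np.sum(b0 * b1n, axis=-1, keepdims=True) * b1n
    w = b2 - np.sum(b2 * b1n, axis=-1, keepdims=True) * b1n
    x = np.sum(v * w, axis=-1)
    y = np.sum(np.cross(b1n, v) * w, axis=-1)
    return wrap_angle(np.degrees(np.arctan2(y, x)))


def place_atom(a, b, c, bond: float, angle: float, torsion: float) -> np.ndarray:
    """Place atom X bonded to `c` such that |X-c| = bond, angle(X, c, b) = angle
    and dihedral(a, b, c, X) = torsion (degrees).  Standard NeRF construction."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    c = np.asarray(c, dtype=float)
    th = math.radians(angle)
    ph = math.radians(torsion)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array(
        [
            -bond * math.cos(th),
            bond * math.sin(th) * math.cos(ph),
            bond * math.sin(th) * math.sin(ph),
        ]
    )
    return c + d[0] * bc + d[1] * m + d[2] * n


def rotation_about_axis(origin, axis, angle_deg: float) -> tuple[np.ndarray, np.ndarray]:
    """Return (R, t) for the rotation by angle_deg about the line through
    `origin` with direction `axis`; apply as coords @ R.T + t."""
    origin = np.asarray(origin, dtype=float)
    k = np.asarray(axis, dtype=float)
    k = k / np.linalg.norm(k)
    th = math.radians(angle_deg)
    K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    R = np.eye(3) + math.sin(th) * K + (1.0 - math.cos(th)) * (K @ K)
    t = origin - origin @ R.T
    return R, t


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (QR of a Gaussian matrix, det fixed to +1)."""
    m = rng.standard_normal((3, 3))
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
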