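"""Geometric primitives: internal-coordinate atom placement, dihedrals,
angles, circular arithmetic and superposition RMSD.

All angles at this interface are in degrees; distances in Å.
"""

from __future__ import annotations

import numpy as np


def wrap_degrees(angle):
    """Wrap angle(s) into [-180, 180)."""
    return (np.asarray(angle) + 180.0) % 360.0 - 180.0


def arc_excess(angle: float, center: float, half_width: float) -> float:
    """Shortest-arc amount (degrees, >= 0) by which ``angle`` falls outside
    [center - half_width, center + half_width]."""
    return float(max(0.0, abs(wrap_degrees(angle - center)) - half_width))


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle: float, torsion: float) -> np.ndarray:
    """Place atom D given A-B-C with |C-D| = bond, angle(B,C,D) = angle and
    dihedral(A,B,C,D) = torsion (NeRF construction)."""
    ang = np.radians(angle)
    tor = np.radians(torsion)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    norm = np.linalg.norm(n)
    if norm < 1e-10:  # colinear reference frame; pick any perpendicular
        helper = np.array([1.0, 0.0, 0.0])
        if abs(bc[0]) > 0.9:
            helper = np.array([0.0, 1.0, 0.0])
        n = np.cross(helper, bc)
        norm = np.linalg.norm(n)
    n /= norm
    m = np.cross(n, bc)
    # component along n carries a minus sign so that the measured dihedral
    # A-B-C-D (IUPAC convention) equals the requested torsion
    d_local = np.array([
        -bond * np.cos(ang),
        bond * np.sin(ang) * np.cos(tor),
        -bond * np.sin(ang) * np.sin(tor),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def dihedral(a, b, c, d) -> float:
    """Dihedral angle A-B-C-D in degrees, in (-180, 180]."""
    b1 = np.asarray(b) - np.asarray(a)
    b2 = np.asarray(c) - np.asarray(b)
    b3 = np.asarray(d) - np.asarray(c)
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    return float(np.degrees(np.arctan2(y, x)))


def bond_angle(a, b, c) -> float:
    """Angle A-B-C in degrees."""
    u = np.asarray(a) - np.asarray(b)
    v = np.asarray(c) - np.asarray(b)
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def kabsch_rmsd(p: np.ndarray, q: np.ndarray) -> float:
    """RMSD between two (N, 3) coordinate sets after optimal superposition."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("coordinate sets must have identical shapes")
    pc = p - p.mean(axis=0)
    qc = q - q.mean(axis=0)
    h = pc.T @ qc
    u, s, vt = np.linalg.svd(h)
    sign = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.array([1.0, 1.0, sign])
    rot = vt.T @ np.diag(diag) @ u.T
    diff = qc - pc @ rot.T
    return float(np.sqrt((diff ** 2).sum() / len(p)))
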