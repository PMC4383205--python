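"""Small geometry utilities: angles, dihedrals, rotations, superposition.

All angles are in degrees, coordinates in Angstrom. The angle/dihedral
helpers use scalar arithmetic because they sit in the Monte Carlo inner loop.
"""
from __future__ import annotations

import math

import numpy as np
from scipy.spatial.transform import Rotation


def angle_deg(a, b, c) -> float:
    """Angle at vertex ``b`` of the triangle a-b-c, in [0, 180] degrees."""
    ux, uy, uz = a[0] - b[0], a[1] - b[1], a[2] - b[2]
    vx, vy, vz = c[0] - b[0], c[1] - b[1], c[2] - b[2]
    nu = math.sqrt(ux * ux + uy * uy + uz * uz)
    nv = math.sqrt(vx * vx + vy * vy + vz * vz)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("degenerate angle: coincident points")
    cosang = (ux * vx + uy * vy + uz * vz) / (nu * nv)
    return math.degrees(math.acos(min(1.0, max(-1.0, cosang))))


def dihedral_deg(p0, p1, p2, p3) -> float:
    """Signed dihedral angle p0-p1-p2-p3 in (-180, 180] degrees."""
    b0x, b0y, b0z = p1[0] - p0[0], p1[1] - p0[1], p1[2] - p0[2]
    b1x, b1y, b1z = p2[0] - p1[0], p2[1] - p1[1], p2[2] - p1[2]
    b2x, b2y, b2z = p3[0] - p2[0], p3[1] - p2[1], p3[2] - p2[2]
    # n1 = b0 x b1, n2 = b1 x b2
    n1x, n1y, n1z = (
        b0y * b1z - b0z * b1y,
        b0z * b1x - b0x * b1z,
        b0x * b1y - b0y * b1x,
    )
    n2x, n2y, n2z = (
        b1y * b2z - b1z * b2y,
        b1z * b2x - b1x * b2z,
        b1x * b2y - b1y * b2x,
    )
    nb1 = math.sqrt(b1x * b1x + b1y * b1y + b1z * b1z)
    if nb1 == 0.0:
        raise ValueError("degenerate dihedral: coincident points")
    # m1 = n1 x (b1 / |b1|)
    m1x, m1y, m1z = (
        (n1y * b1z - n1z * b1y) / nb1,
        (n1z * b1x - n1x * b1z) / nb1,
        (n1x * b1y - n1y * b1x) / nb1,
    )
    x = n1x * n2x + n1y * n2y + n1z * n2z
    y = m1x * n2x + m1y * n2y + m1z * n2z
    return math.degrees(math.atan2(y, x))


def rotation_about_axis(axis, angle_deg_: float) -> np.ndarray:
    """3x3 rotation matrix about ``axis`` (need not be normalised), Rodrigues form."""
    ux, uy, uz = float(axis[0]), float(axis[1]), float(axis[2])
    n = math.sqrt(ux * ux + uy * uy + uz * uz)
    if n == 0.0:
        raise ValueError("zero rotation axis")
    ux, uy, uz = ux / n, uy / n, uz / n
    t = math.radians(angle_deg_)
    c, s = math.cos(t), math.sin(t)
    cc = 1.0 - c
    return np.array(
        [
            [c + ux * ux * cc, ux * uy * cc - uz * s, ux * uz * cc + uy * s],
            [uy * ux * cc + uz * s, c + uy * uy * cc, uy * uz * cc - ux * s],
            [uz * ux * cc - uy * s, uz * uy * cc + ux * s, c + uz * uz * cc],
        ]
    )


def superpose(mobile: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, float]:
    """Least-squares superposition of ``mobile`` onto ``target``.

    Returns the transformed mobile coordinates and the RMSD (Angstrom) after
    optimal rotation and translation (Kabsch).
    """
    mobile = np.asarray(mobile, float)
    target = np.asarray(target, float)
    if mobile.shape != target.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("superpose expects two equally shaped (n, 3) arrays")
    mc = mobile - mobile.mean(axis=0)
    tc = target - target.mean(axis=0)
    rot, _ = Rotation.align_vectors(tc, mc)
    moved = rot.apply(mc) + target.mean(axis=0)
    rmsd = float(np.sqrt(np.mean(np.sum((moved - target) ** 2, axis=1))))
    return moved, rmsd
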