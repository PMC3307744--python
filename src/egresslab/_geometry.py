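"""Shared vector geometry: dihedral angles (IUPAC sign) and their gradients."""

from __future__ import annotations

import numpy as np

__all__ = ["dihedral_angle", "dihedral_angles", "dihedral_angle_and_grad"]


def dihedral_angles(p1, p2, p3, p4) -> np.ndarray:
    """Signed dihedral angle(s) in degrees, in (−180, 180].

    Inputs broadcast over a leading axis (frames).  Sign follows the IUPAC
    convention: looking down the 2→3 bond, a clockwise rotation of the
    1–2 bond onto the 3–4 bond is positive.  Returns NaN where a bonded
    triple is collinear (angle undefined).
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2, axis=-1)
    m1 = np.cross(n1, b2 / np.where(nb2 == 0, 1.0, nb2)[..., None])
    x = np.sum(n1 * n2, axis=-1)
    y = np.sum(m1 * n2, axis=-1)
    ang = np.degrees(np.arctan2(y, x))
    bad = (np.linalg.norm(n1, axis=-1) < 1e-10) | (np.linalg.norm(n2, axis=-1) < 1e-10)
    return np.where(bad, np.nan, ang)


def dihedral_angle(p1, p2, p3, p4) -> float:
    return float(dihedral_angles(p1, p2, p3, p4))


def _cross3(a, b):
    return np.array([a[1] * b[2] - a[2] * b[1],
                     a[2] * b[0] - a[0] * b[2],
                     a[0] * b[1] - a[1] * b[0]])


def dihedral_angle_and_grad(p1, p2, p3, p4):
    """Dihedral angle (radians) and its gradient w.r.t. the four points.

    Returns ``(phi, (g1, g2, g3, g4))`` with ``gi = dphi/dpi`` (rad/Å).
    """
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = _cross3(b1, b2)
    n2 = _cross3(b2, b3)
    nb2 = float(np.sqrt(b2 @ b2))
    n1sq = n1 @ n1
    n2sq = n2 @ n2
    if n1sq < 1e-20 or n2sq < 1e-20 or nb2 < 1e-10:
        raise ValueError("collinear atoms: dihedral undefined")
    m1 = _cross3(n1, b2 / nb2)
    phi = np.arctan2(m1 @ n2, n1 @ n2)
    g1 = (nb2 / n1sq) * n1
    g4 = -(nb2 / n2sq) * n2
    c1 = (b1 @ b2) / (nb2 * nb2)
    c2 = (b3 @ b2) / (nb2 * nb2)
    g2 = -(1.0 + c1) * g1 + c2 * g4
    g3 = c1 * g1 - (1.0 + c2) * g4
    return phi, (g1, g2, g3, g4)
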