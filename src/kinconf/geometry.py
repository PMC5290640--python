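"""Low-level vector geometry: torsion angles and internal-coordinate atom placement.

All angles are in degrees on the interval (-180, 180], following the IUPAC
convention for dihedrals (right-handed; cis = 0, trans = +180).
"""

from __future__ import annotations

import math

import numpy as np

__all__ = ["torsion", "place_atom", "wrap_angle"]

# below this, consecutive points are treated as coincident / collinear
_DEGENERATE_EPS = 1e-8


def wrap_angle(theta: float) -> float:
    """Wrap an angle in degrees onto (-180, 180]."""
    t = math.fmod(theta, 360.0)
    if t <= -180.0:
        t += 360.0
    elif t > 180.0:
        t -= 360.0
    return t


def torsion(p1, p2, p3, p4) -> float | None:
    """Dihedral angle defined by four points, degrees in (-180, 180].

    Sign follows the right-hand rule looking from p2 to p3: cis (eclipsed)
    is 0, trans is reported as +180. Returns None for degenerate geometry
    (coincident consecutive points or collinear triples) instead of raising,
    so callers can record the angle as missing.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    p3 = np.asarray(p3, dtype=float)
    p4 = np.asarray(p4, dtype=float)

    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3

    nb2 = np.linalg.norm(b2)
    if (
        np.linalg.norm(b1) < _DEGENERATE_EPS
        or nb2 < _DEGENERATE_EPS
        or np.linalg.norm(b3) < _DEGENERATE_EPS
    ):
        return None

    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < _DEGENERATE_EPS or np.linalg.norm(n2) < _DEGENERATE_EPS:
        return None  # collinear triple: plane undefined

    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b2 / nb2))
    ang = math.degrees(math.atan2(y, x))
    if ang <= -180.0:
        ang += 360.0
    return ang


def place_atom(a, b, c, bond_length: float, bond_angle: float, dihedral: float) -> np.ndarray:
    """Place a fourth atom D from three reference atoms by internal coordinates.

    NeRF-style construction: D is at distance ``bond_length`` from ``c``,
    forming angle ``bond_angle`` (degrees) b-c-D, with torsion ``dihedral``
    (degrees) a-b-c-D. The resulting coordinates satisfy
    ``torsion(a, b, c, D) == dihedral`` to machine precision.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    c = np.asarray(c, dtype=float)

    theta = math.radians(bond_angle)
    chi = math.radians(dihedral)

    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)

    d_local = np.array(
        [
            -bond_length * math.cos(theta),
            bond_length * math.sin(theta) * math.cos(chi),
            bond_length * math.sin(theta) * math.sin(chi),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n
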