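"""Low-level vector geometry: dihedrals, bond angles, internal-coordinate
atom placement (NeRF) and axis rotations.

Conventions
-----------
* Angles are in degrees at every public boundary; radians internally.
* Dihedrals follow the IUPAC sign convention and live in (-180, 180].
* ``place_atom(a, b, c, ...)`` positions a new atom ``d`` bonded to ``c``
  such that ``angle(b, c, d)`` and ``dihedral(a, b, c, d)`` take the
  requested values (the NeRF construction used by chain builders).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "normalize",
    "bond_angle",
    "dihedral",
    "place_atom",
    "rotation_about_axis",
    "wrap_angle",
]


def normalize(v: np.ndarray) -> np.ndarray:
    """Unit vector along ``v`` (last-axis normalization for stacked input)."""
    n = np.linalg.norm(v, axis=-1, keepdims=True)
    return v / n


def wrap_angle(a):
    """Wrap degrees into (-180, 180]."""
    a = np.asarray(a, dtype=float)
    w = -((-a + 180.0) % 360.0 - 180.0)
    return w if w.ndim else float(w)


def bond_angle(p0, p1, p2) -> float:
    """Angle p0-p1-p2 in degrees, in [0, 180]."""
    u = normalize(np.asarray(p0, float) - p1)
    v = normalize(np.asarray(p2, float) - p1)
    return float(np.degrees(np.arccos(np.clip(np.dot(u, v), -1.0, 1.0))))


def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral p0-p1-p2-p3 in degrees, in (-180, 180]."""
    p0, p1, p2, p3 = (np.asarray(p, float) for p in (p0, p1, p2, p3))
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1 /= np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    return wrap_angle(np.degrees(np.arctan2(y, x)))


def cross3(a, b):
    """Cross product specialized for 3-vectors (fast path for small arrays)."""
    return np.stack(
        (a[..., 1] * b[..., 2] - a[..., 2] * b[..., 1],
         a[..., 2] * b[..., 0] - a[..., 0] * b[..., 2],
         a[..., 0] * b[..., 1] - a[..., 1] * b[..., 0]),
        axis=-1,
    )


def _frame(a, b, c):
    """Right-handed frame at ``c`` used by the NeRF placement."""
    bc = np.asarray(c, float) - b
    bc = bc / np.sqrt(bc @ bc)
    ab = np.asarray(b, float) - a
    n = np.array((ab[1] * bc[2] - ab[2] * bc[1],
                  ab[2] * bc[0] - ab[0] * bc[2],
                  ab[0] * bc[1] - ab[1] * bc[0]))
    nn = np.sqrt(n @ n)
    if nn < 1e-10:
        raise ValueError("collinear reference atoms in place_atom")
    n = n / nn
    m = np.array((n[1] * bc[2] - n[2] * bc[1],
                  n[2] * bc[0] - n[0] * bc[2],
                  n[0] * bc[1] - n[1] * bc[0]))
    return bc, m, n


def place_atom(a, b, c, bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """Place atom ``d`` from reference atoms ``a, b, c``.

    Postconditions: ``|d - c| = bond``, ``bond_angle(b, c, d) = angle_deg``,
    ``dihedral(a, b, c, d) = dihedral_deg``.
    """
    theta = np.radians(angle_deg)
    chi = np.radians(dihedral_deg)
    bc, m, n = _frame(a, b, c)
    d_local = np.array(
        [
            -bond * np.cos(theta),
            bond * np.sin(theta) * np.cos(chi),
            bond * np.sin(theta) * np.sin(chi),
        ]
    )
    return np.asarray(c, float) + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def rotation_about_axis(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """3x3 rotation matrix for a right-handed rotation about ``axis``."""
    u = normalize(np.asarray(axis, float))
    t = np.radians(angle_deg)
    c, s = np.cos(t), np.sin(t)
    ux, uy, uz = u
    return np.array(
        [
            [c + ux * ux * (1 - c), ux * uy * (1 - c) - uz * s, ux * uz * (1 - c) + uy * s],
            [uy * ux * (1 - c) + uz * s, c + uy * uy * (1 - c), uy * uz * (1 - c) - ux * s],
            [uz * ux * (1 - c) - uy * s, uz * uy * (1 - c) + ux * s, c + uz * uz * (1 - c)],
        ]
    )
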