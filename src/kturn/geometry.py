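"""Pure geometric kernel: distances, angles, torsions, ring centers,
sugar pseudorotation, gauche binning and internal-coordinate atom placement.

All angles cross module boundaries in degrees.  Torsions follow the IUPAC
right-hand convention with cis = 0 deg and values in (-180, +180].
"""

from __future__ import annotations

import math

import numpy as np

__all__ = [
    "DegenerateGeometryError",
    "distance",
    "angle",
    "dihedral",
    "classify_gauche",
    "ring_center",
    "pseudorotation",
    "SugarPucker",
    "place_atom_internal",
    "PUCKER_CLASSES",
]


class DegenerateGeometryError(ValueError):
    """Raised when a geometric primitive receives collinear/coincident atoms."""


_EPS = 1e-10


def _as_point(p) -> np.ndarray:
    a = np.asarray(p, dtype=float)
    if a.shape != (3,):
        raise ValueError(f"expected a 3-vector, got shape {a.shape}")
    if not np.all(np.isfinite(a)):
        raise ValueError("non-finite coordinates")
    return a


def distance(a, b) -> float:
    """Euclidean distance in Angstrom."""
    return float(np.linalg.norm(_as_point(a) - _as_point(b)))


def angle(a, b, c) -> float:
    """Interior angle at *b* in degrees, in [0, 180]."""
    a, b, c = _as_point(a), _as_point(b), _as_point(c)
    u = a - b
    v = c - b
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu < _EPS or nv < _EPS:
        raise DegenerateGeometryError("zero-length arm in angle()")
    cosang = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(math.degrees(math.acos(cosang)))


def dihedral(a, b, c, d) -> float:
    """Torsion a-b-c-d in degrees, in (-180, +180], cis = 0.

    Invariant under full atom-order reversal (d,c,b,a) and under rigid
    rotation/translation; negated by mirror reflection.
    """
    a, b, c, d = (_as_point(p) for p in (a, b, c, d))
    b0 = a - b
    b1 = c - b
    b2 = d - c
    nb1 = np.linalg.norm(b1)
    if nb1 < _EPS:
        raise DegenerateGeometryError("coincident central atoms in dihedral()")
    b1 = b1 / nb1
    # components of b0/b2 perpendicular to the central bond
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    if np.linalg.norm(v) < _EPS or np.linalg.norm(w) < _EPS:
        raise DegenerateGeometryError("collinear atom triple in dihedral()")
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    ang = math.degrees(math.atan2(y, x))
    if ang <= -180.0:  # map (-180, 180]
        ang += 360.0
    return float(ang)


def classify_gauche(t: float) -> str:
    """Bin a torsion (degrees) into g+, g- or t.

    g+ is [0, 120), g- is [-120, 0), t is the rest, so the canonical
    +60/-60/180 centers sit mid-bin and the bins partition (-180, 180].
    """
    t = float(t)
    t = ((t + 180.0) % 360.0) - 180.0  # normalize into (-180, 180]
    if t == -180.0:
        t = 180.0
    if 0.0 <= t < 120.0:
        return "g+"
    if -120.0 <= t < 0.0:
        return "g-"
    return "t"


#: endocyclic ring nitrogens per base class
RING_NITROGENS = {
    "purine": ("N1", "N3", "N7", "N9"),
    "pyrimidine": ("N1", "N3"),
}


def ring_center(points) -> np.ndarray:
    """Unweighted geometric center of the given atom positions."""
    arr = np.asarray(points, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 3 or arr.shape[0] == 0:
        raise ValueError("ring_center expects an (n, 3) array of positions")
    return arr.mean(axis=0)


# 36-degree pseudorotation bins anchored at P = 0
PUCKER_CLASSES = (
    "C3'-endo",
    "C4'-exo",
    "O4'-endo",
    "C1'-exo",
    "C2'-endo",
    "C3'-exo",
    "C4'-endo",
    "O4'-exo",
    "C1'-endo",
    "C2'-exo",
)

_SIN36_72 = math.sin(math.radians(36.0)) + math.sin(math.radians(72.0))


class SugarPucker:
    """Altona-Sundaralingam pseudorotation of a five-membered sugar ring.

    nu0..nu4 are the endocyclic torsions in degrees
    (nu0 = C4'-O4'-C1'-C2' ... nu4 = C3'-C4'-O4'-C1').
    """

    __slots__ = ("nu", "phase", "amplitude", "pucker_class")

    def __init__(self, nu, phase: float, amplitude: float, pucker_class):
        self.nu = tuple(float(v) for v in nu)
        self.phase = float(phase)
        self.amplitude = float(amplitude)
        self.pucker_class = pucker_class

    def __repr__(self):  # pragma: no cover
        return (
            f"SugarPucker(P={self.phase:.2f}, tau_m={self.amplitude:.2f}, "
            f"class={self.pucker_class!r})"
        )


def pucker_class_of(phase: float) -> str:
    """Name of the 36-degree bin containing pseudorotation phase *phase*."""
    return PUCKER_CLASSES[int((phase % 360.0) // 36.0)]


def pseudorotation(nu0, nu1, nu2, nu3, nu4) -> SugarPucker:
    """Pseudorotation phase/amplitude from five endocyclic torsions (deg).

    P = atan2(nu4 + nu1 - nu3 - nu0, 2 nu2 (sin36 + sin72)), mapped to
    [0, 360); tau_m from nu2/cos P, falling back to the numerator when
    cos P is small.  A flat ring (all nu ~ 0) yields amplitude 0 and
    pucker_class None.
    """
    nu = [float(v) for v in (nu0, nu1, nu2, nu3, nu4)]
    if any(not math.isfinite(v) for v in nu):
        raise ValueError("non-finite endocyclic torsion")
    num = nu[4] + nu[1] - nu[3] - nu[0]
    den = 2.0 * nu[2] * _SIN36_72
    if abs(num) < 1e-9 and abs(den) < 1e-9:
        return SugarPucker(nu, 0.0, 0.0, None)
    p = math.degrees(math.atan2(num, den)) % 360.0
    cosp = math.cos(math.radians(p))
    if abs(cosp) > 0.1:
        tau = nu[2] / cosp
    else:
        tau = num / (2.0 * math.sin(math.radians(p)) * _SIN36_72)
    return SugarPucker(nu, p, tau, pucker_class_of(p))


def generate_nu(phase: float, amplitude: float):
    """Closed-form endocyclic torsions nu_j = tau_m cos(P + 144 (j - 2)).

    Inverse of :func:`pseudorotation`; used as its independent oracle and by
    the synthetic template builder.
    """
    return tuple(
        amplitude * math.cos(math.radians(phase + 144.0 * (j - 2)))
        for j in range(5)
    )


def place_atom_internal(a, b, c, bond: float, bond_angle: float,
                        torsion: float) -> np.ndarray:
    """Place atom d from internal coordinates relative to the frame a, b, c.

    The returned point satisfies distance(c, d) == bond,
    angle(b, c, d) == bond_angle and dihedral(a, b, c, d) == torsion
    (degrees), each to ~1e-6.
    """
    a, b, c = _as_point(a), _as_point(b), _as_point(c)
    if bond <= 0:
        raise ValueError("bond length must be positive")
    bc = c - b
    nbc = np.linalg.norm(bc)
    if nbc < _EPS:
        raise DegenerateGeometryError("coincident frame atoms b, c")
    bc = bc / nbc
    ab = b - a
    n = np.cross(ab, bc)
    nn = np.linalg.norm(n)
    if nn < _EPS:
        raise DegenerateGeometryError("collinear frame a, b, c")
    n = n / nn
    m = np.cross(n, bc)
    theta = math.radians(bond_angle)
    phi = math.radians(torsion)
    # local displacement from c: component along bc is -cos(theta) so that
    # the interior angle at c equals bond_angle; phi rotates about bc with
    # the sign matching dihedral()'s right-hand convention.
    d_local = bond * np.array(
        [-math.cos(theta), math.sin(theta) * math.cos(phi),
         math.sin(theta) * math.sin(phi)]
    )
    frame = np.stack([bc, m, n], axis=1)  # columns are the basis vectors
    return c + frame @ d_local
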