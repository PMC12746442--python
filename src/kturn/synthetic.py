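"""Synthetic kink-turn ensembles with known ground truth.

Two layers:

* :func:`build_template` constructs a minimal-atom kink-turn frame from a
  mapping of feature targets (SI native/non-native/absent, A-minor
  AM0/AMI/none, chi syn/anti, stacking partner, sugar-pucker class, suite
  bins, individual H-bonds on/off, ion placements).  Atoms are placed by
  internal coordinates so that every classifier reproduces the targets
  exactly at zero noise, with generous margins to every decision boundary
  (>= 1 A on distance cutoffs, >= 60 deg on torsion bins, mid-bin on the
  36-deg pseudorotation classes) so that small coordinate noise cannot flip
  a state.

* :func:`simulate_ensemble` drives the per-feature states with seeded
  discrete Markov chains (mimicking the fast reversible switching seen in
  kink-turn MD, e.g. native/non-native SI exchange), emits the matching
  template geometry per frame, adds isotropic Gaussian coordinate noise,
  and retains the pre-noise ground-truth labels.

Templates emulate only what the classifiers measure: they are geometric
gadgets, not chemically complete nucleotides.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import geometry as geo
from .geometry import place_atom_internal
from .interactions import (
    AG_LABELS,
    GC_LABELS,
    HBondCriterion,
    feature_vector,
    FrameView,
)
from .structure_io import Atom, Ensemble, KinkTurnAnnotation, Structure

__all__ = [
    "ConstructionError",
    "SyntheticSpecError",
    "TemplateResult",
    "SyntheticFeature",
    "CouplingRule",
    "SyntheticSpec",
    "build_template",
    "simulate_ensemble",
    "recovery_report",
    "enumerate_state_combinations",
    "default_spec",
    "DEFAULT_TARGETS",
    "SYNTHETIC_ANNOTATION",
]


class ConstructionError(ValueError):
    """Mutually contradictory template targets."""


class SyntheticSpecError(ValueError):
    """Invalid synthetic-ensemble specification."""


# --------------------------------------------------------------------------
# template layout constants
# --------------------------------------------------------------------------

D_ON = 2.9     # A, heavy-atom distance realizing a formed H-bond
D_OFF = 5.5    # A, distance realizing a broken H-bond
H_LEN = 1.0    # A, donor-hydrogen bond length

#: role -> (chain, resnum, resname) of the synthetic template
TEMPLATE_RESIDUES = {
    "C_-1b": ("A", 1, "C"),
    "G_1b": ("A", 2, "G"),
    "A_2b": ("A", 3, "A"),
    "A_3b": ("A", 4, "A"),
    "G_L1": ("A", 5, "G"),
    "A_L2": ("A", 6, "A"),
    "A_L3": ("A", 7, "A"),
    "G_-1n": ("A", 11, "G"),
    "A_1n": ("A", 12, "A"),
    "G_2n": ("A", 13, "G"),
    "G_3n": ("A", 14, "G"),
}

SYNTHETIC_ANNOTATION = KinkTurnAnnotation(
    roles={role: (c, n) for role, (c, n, _) in TEMPLATE_RESIDUES.items()}
)

#: categorical feature -> supported states (first entry = crystal-like)
FEATURE_STATES = {
    "si": ("native", "non-native", "absent"),
    "aminor": ("AM0", "AMI", "none"),
    "chi": ("syn", "anti"),
    "stacking": ("A_1n", "G_L1", "none"),
    "pucker": ("C2'-endo", "O4'-endo", "C3'-endo"),
    "suite_A_1n/G_-1n": ("native", "canonical"),
    "suite_G_L1/A_L2": ("native", "canonical"),
    "suite_A_L2/A_L3": ("native", "canonical"),
    "bph4": ("on", "off"),
    "sugar_phosphate": ("on", "off"),
    "sugar_base": ("on", "off"),
    "k_ion": ("absent", "bound"),
    "mg_ion": ("absent", "inner", "outer", "unbound"),
}

#: individually overridable H-bonds (on/off); the decisive SI and A-minor
#: bonds are controlled through their categorical features only
OVERRIDABLE_BONDS = AG_LABELS + GC_LABELS + (
    "AM0_B", "AMI_B", "BPH4_N1", "BPH4_N2")

#: crystal-like default target set
DEFAULT_TARGETS = {
    "si": "native",
    "aminor": "AM0",
    "chi": "syn",
    "stacking": "A_1n",
    "pucker": "C2'-endo",
    "suite_A_1n/G_-1n": "native",
    "suite_G_L1/A_L2": "native",
    "suite_A_L2/A_L3": "native",
    "bph4": "on",
    "sugar_phosphate": "on",
    "sugar_base": "on",
}

_SUITE_TORSIONS = {"g+": 60.0, "g-": -60.0, "t": 180.0}
_SUITE_NATIVE = {
    "suite_A_1n/G_-1n": ("g+", "t"),
    "suite_G_L1/A_L2": ("g+", "g-"),
    "suite_A_L2/A_L3": ("g+", "g+"),
}
_SUITE_CANONICAL = ("g-", "g+")  # canonical A-RNA alpha/gamma

_PUCKER_TARGET_P = {name: 18.0 + 36.0 * i
                    for i, name in enumerate(geo.PUCKER_CLASSES)}

_CHI_VALUES = {"syn": 30.0, "anti": 180.0}

# stacking center distances (cutoffs 4.0 vs A_1n, 4.5 vs G_L1)
_STACK_D = {
    "A_1n": (3.0, 5.8),
    "G_L1": (5.2, 3.2),
    "none": (5.2, 5.8),
}

_SI_GEOM = {
    # (d(O2',N1), N6 offset from N1 along the same axis)
    "native": (2.9, -2.5),       # d(O2',N6) = 5.4
    "non-native": (5.4, 2.5),    # d(O2',N6) = 2.9
    "absent": (5.2, -0.8),       # d(O2',N6) = 6.0
}


def _unit(v):
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


@dataclass
class MarginRecord:
    feature: str
    quantity: str
    realized: float
    boundary: float
    margin: float


@dataclass
class TemplateResult:
    structure: Structure
    annotation: KinkTurnAnnotation
    targets: dict
    report: list[MarginRecord]
    expected: dict

    def view(self) -> FrameView:
        return FrameView(self.structure, self.annotation, frame=0)


def _validate_targets(targets: dict) -> dict:
    full = dict(DEFAULT_TARGETS)
    bond_overrides: dict[str, str] = {}
    deletions: list[tuple[str, str]] = []
    for key, value in targets.items():
        if key == "delete_atoms":
            deletions = [tuple(x) for x in value]
            continue
        if key in OVERRIDABLE_BONDS:
            if value not in ("on", "off"):
                raise ConstructionError(f"bond {key}: state must be on/off")
            bond_overrides[key] = value
            continue
        if key not in FEATURE_STATES:
            raise ConstructionError(f"unknown feature {key!r}")
        if key == "chi" and isinstance(value, (int, float)):
            full[key] = float(value)
            continue
        if value not in FEATURE_STATES[key]:
            raise ConstructionError(
                f"feature {key!r}: unknown state {value!r} "
                f"(supported: {FEATURE_STATES[key]})")
        full[key] = value
    # cross-feature consistency
    b1 = bond_overrides.get("BPH4_N1")
    b2 = bond_overrides.get("BPH4_N2")
    if full["bph4"] == "on" and b1 == "off" and b2 == "off":
        raise ConstructionError("bph4 'on' conflicts with both BPH4 bonds off")
    if full["bph4"] == "off" and ("on" in (b1, b2)):
        raise ConstructionError("bph4 'off' conflicts with a BPH4 bond on")
    full["_bonds"] = bond_overrides
    full["_delete"] = deletions
    return full


def _bond_plan(full: dict) -> dict[str, bool]:
    """Target on/off state of every catalogued H-bond."""
    ov = full["_bonds"]
    plan: dict[str, bool] = {}
    plan["SI_native"] = full["si"] == "native"
    plan["SI_nonnative"] = full["si"] == "non-native"
    am = full["aminor"]
    plan["AM0_A"] = am == "AM0"
    plan["AMI_A"] = am == "AMI"
    plan["AMI_C"] = am == "AMI"
    plan["AM0_B"] = ov.get("AM0_B", "on" if am == "AM0" else "off") == "on"
    plan["AMI_B"] = ov.get("AMI_B", "on" if am == "AMI" else "off") == "on"
    for lab in AG_LABELS + GC_LABELS:
        plan[lab] = ov.get(lab, "on") == "on"
    if full["bph4"] == "on":
        plan["BPH4_N1"] = ov.get("BPH4_N1", "on") == "on"
        plan["BPH4_N2"] = ov.get("BPH4_N2", "off") == "on"
    else:
        plan["BPH4_N1"] = plan["BPH4_N2"] = False
    plan["SP_AL3AL2"] = full["sugar_phosphate"] == "on"
    plan["SB_G1bG2n"] = full["sugar_base"] == "on"
    return plan


def _don(on: bool) -> float:
    return D_ON if on else D_OFF


# --------------------------------------------------------------------------
# sugar-ring calibration
# --------------------------------------------------------------------------

_RING_NAMES = ("O4'", "C1'", "C2'", "C3'", "C4'")
_RING_RADIUS = 2.4   # enlarged vs chemistry so 0.1 A noise barely moves P


def _ring_coords(phase_offset: float, q: float) -> np.ndarray:
    """Pentagon O4',C1',C2',C3',C4' with out-of-plane wave cos(144 j + phi)."""
    pts = []
    for j in range(5):
        th = math.radians(72.0 * j)
        z = q * math.cos(math.radians(144.0 * j + phase_offset))
        pts.append((_RING_RADIUS * math.cos(th),
                    _RING_RADIUS * math.sin(th), z))
    return np.asarray(pts)


def _measure_pucker(pts: np.ndarray):
    o4, c1, c2, c3, c4 = pts
    nus = (
        geo.dihedral(c4, o4, c1, c2),
        geo.dihedral(o4, c1, c2, c3),
        geo.dihedral(c1, c2, c3, c4),
        geo.dihedral(c2, c3, c4, o4),
        geo.dihedral(c3, c4, o4, c1),
    )
    return geo.pseudorotation(*nus)


def _calibrated_ring(p_target: float, tau_target: float = 90.0) -> np.ndarray:
    # tau_m is deliberately exaggerated relative to real sugars (~40 deg):
    # phase noise under per-atom coordinate noise scales as 1/tau_m, and the
    # templates must keep P >= ~6 noise SD away from the 36-deg bin edges.
    """Ring coordinates whose measured pseudorotation phase hits p_target.

    The wave phase offset maps nearly linearly onto the measured P; a few
    secant iterations converge far below a degree.
    """
    phi, q = 0.0, 0.9
    for _ in range(6):
        sp0 = _measure_pucker(_ring_coords(phi, q))
        err = ((p_target - sp0.phase + 180.0) % 360.0) - 180.0
        if abs(err) < 1e-8 and abs(sp0.amplitude - tau_target) < 1e-6:
            break
        sp1 = _measure_pucker(_ring_coords(phi + 5.0, q))
        dphase = ((sp1.phase - sp0.phase + 180.0) % 360.0) - 180.0
        if abs(dphase) < 1e-12:
            raise ConstructionError("pucker calibration degenerate")
        phi += err * 5.0 / dphase
        q *= tau_target / max(abs(sp0.amplitude), 1e-9)
        if sp0.amplitude < 0:
            # wrong handedness of the wave: flip
            q = -q
    sp = _measure_pucker(_ring_coords(phi, q))
    err = ((p_target - sp.phase + 180.0) % 360.0) - 180.0
    if abs(err) > 1e-6:
        raise ConstructionError(
            f"pucker calibration failed: target {p_target}, got {sp.phase}")
    return _ring_coords(phi, q)


# --------------------------------------------------------------------------
# the builder
# --------------------------------------------------------------------------

def build_template(targets: dict | None = None,
                   criterion: HBondCriterion = HBondCriterion()
                   ) -> TemplateResult:
    """Build a minimal-atom kink-turn frame realizing the given targets.

    Unspecified features default to the crystal-like state
    (:data:`DEFAULT_TARGETS`).  Raises :class:`ConstructionError` on
    contradictory targets (including deletion of an atom that a targeted-on
    feature requires).
    """
    full = _validate_targets(targets or {})
    plan = _bond_plan(full)
    atoms: dict[tuple[str, str], np.ndarray] = {}
    required: dict[tuple[str, str], str] = {}
    report: list[MarginRecord] = []

    def put(role, name, pos, needed_for=None):
        atoms[(role, name)] = np.asarray(pos, dtype=float)
        if needed_for:
            required[(role, name)] = needed_for

    def rec(feature, quantity, realized, boundary):
        report.append(MarginRecord(feature, quantity, float(realized),
                                   float(boundary),
                                   float(abs(realized - boundary))))

    # --- bulge zone: A_L2 sugar ring + chi + base ring -------------------
    chi_target = full["chi"] if isinstance(full["chi"], float) \
        else _CHI_VALUES[full["chi"]]
    ring_local = _calibrated_ring(_PUCKER_TARGET_P[full["pucker"]])
    S2 = np.array([9.0, 0.0, 0.0])
    ring = ring_local + S2
    for name, pos in zip(_RING_NAMES, ring):
        put("A_L2", name, pos, needed_for="pucker")
    o4, c1, c2, c3, c4 = ring
    n9 = c1 + 2.0 * _unit(c1 - S2)
    put("A_L2", "N9", n9, needed_for="chi")
    put("A_L2", "C4",
        place_atom_internal(o4, c1, n9, 2.0, 115.0, chi_target),
        needed_for="chi")
    rec("chi", "chi_deg", chi_target, 90.0 if chi_target > 0 else -90.0)

    # A_L2 base ring center at the origin (mean of N1,N3,N7,N9)
    c_l2 = np.zeros(3)
    m = (4.0 * c_l2 - n9) / 3.0
    put("A_L2", "N1", m + np.array([1.3, 0.0, 0.0]), needed_for="stacking")
    put("A_L2", "N3", m + np.array([-0.65, 0.0, 1.126]), needed_for="stacking")
    put("A_L2", "N7", m + np.array([-0.65, 0.0, -1.126]), needed_for="stacking")

    # --- stacking partners ----------------------------------------------
    d1, d2 = _STACK_D[full["stacking"]]
    c_1n = np.array([0.0, d1, 0.0])
    c_gl1 = np.array([0.0, -d2, 0.0])
    rec("stacking", "d(A_L2,A_1n)", d1, 4.0)
    rec("stacking", "d(A_L2,G_L1)", d2, 4.5)
    put("A_1n", "N1", c_1n + np.array([1.3, 0.0, 0.0]), needed_for="stacking")
    put("A_1n", "N3", c_1n + np.array([0.0, 0.0, 1.3]), needed_for="stacking")
    put("A_1n", "N7", c_1n + np.array([-1.3, 0.0, 0.0]), needed_for="stacking")
    put("A_1n", "N9", c_1n + np.array([0.0, 0.0, -1.3]), needed_for="stacking")
    for name, off in zip(("N1", "N3", "N7", "N9"),
                         ([1.3, 0, 0], [0, 0, 1.3], [-1.3, 0, 0], [0, 0, -1.3])):
        put("G_L1", name, c_gl1 + np.asarray(off, float), needed_for="stacking")

    # --- signature interaction ------------------------------------------
    u_si = _unit([0.0, 1.0, 1.0])
    n1_a1n = atoms[("A_1n", "N1")]
    d_o2p, n6_off = _SI_GEOM[full["si"]]
    o2p_gl1 = n1_a1n + d_o2p * u_si
    n6_a1n = n1_a1n + n6_off * u_si
    put("G_L1", "O2'", o2p_gl1, needed_for="si")
    put("A_1n", "N6", n6_a1n, needed_for="si")
    rec("si", "d(O2',N1)", d_o2p, criterion.distance_cutoff)
    rec("si", "d(O2',N6)", float(np.linalg.norm(o2p_gl1 - n6_a1n)),
        criterion.distance_cutoff)

    # --- AG1 pair (A_1n with G_1b) --------------------------------------
    wx = np.array([1.0, 0.0, 0.0])
    n3_g1b = n6_a1n + _don(plan["AG1_N6N3"]) * wx
    put("G_1b", "N3", n3_g1b)
    put("A_1n", "H61", n6_a1n + H_LEN * wx)
    put("A_1n", "H62", n6_a1n + H_LEN * np.array([0.0, 0.0, 1.0]))
    n7_a1n = atoms[("A_1n", "N7")]
    n2_g1b = n7_a1n + _don(plan["AG1_N2N7"]) * np.array([-1.0, 0.0, 0.0])
    put("G_1b", "N2", n2_g1b)
    put("G_1b", "H21", n2_g1b + H_LEN * _unit(n7_a1n - n2_g1b))
    put("G_1b", "H22", n2_g1b + H_LEN * np.array([0.0, 0.0, 1.0]))

    # --- A-minor zone ----------------------------------------------------
    g0 = np.array([-15.0, 0.0, 0.0])
    put("G_-1n", "O2'", g0, needed_for="aminor")
    n3_a2b = g0 + _don(plan["AM0_A"]) * np.array([1.0, 0.0, 0.0])
    put("A_2b", "N3", n3_a2b, needed_for="aminor")
    put("A_2b", "O2'", g0 + _don(plan["AM0_B"]) * np.array([0.0, 1.0, 0.0]))
    put("A_2b", "N1", g0 + _don(plan["AMI_A"]) * np.array([0.0, 0.0, 1.0]),
        needed_for="aminor")
    n2_g1n = n3_a2b + _don(plan["AMI_C"]) * np.array([0.0, -1.0, 0.0])
    put("G_-1n", "N2", n2_g1n, needed_for="aminor")
    put("G_-1n", "H21", n2_g1n + H_LEN * _unit(n3_a2b - n2_g1n))
    put("C_-1b", "O2'",
        atoms[("A_2b", "O2'")] + _don(plan["AMI_B"]) * np.array([0.0, 1.0, 0.0]))

    # --- GC pair of the C-stem ------------------------------------------
    o6 = np.array([-15.0, -6.0, 0.0])
    put("G_-1n", "O6", o6)
    n4 = o6 + _don(plan["GC_O6N4"]) * np.array([0.0, -1.0, 0.0])
    put("C_-1b", "N4", n4)
    put("C_-1b", "H41", n4 + H_LEN * _unit(o6 - n4))
    put("C_-1b", "H42", n4 + H_LEN * np.array([1.0, 0.0, 0.0]))
    n1_g1n = np.array([-11.0, -6.0, 0.0])
    put("G_-1n", "N1", n1_g1n)
    n3_c1b = n1_g1n + _don(plan["GC_N1N3"]) * np.array([0.0, -1.0, 0.0])
    put("C_-1b", "N3", n3_c1b)
    put("G_-1n", "H1", n1_g1n + H_LEN * _unit(n3_c1b - n1_g1n))
    o2_c1b = n2_g1n + _don(plan["GC_O2N2"]) * np.array([0.0, -1.0, 0.0])
    put("C_-1b", "O2", o2_c1b)
    put("G_-1n", "H22", n2_g1n + H_LEN * _unit(o2_c1b - n2_g1n))

    # --- AG2 pair + sugar-base ------------------------------------------
    n6_a2b = np.array([-15.0, 10.0, 0.0])
    put("A_2b", "N6", n6_a2b)
    n3_g2n = n6_a2b + _don(plan["AG2_N6N3"]) * np.array([1.0, 0.0, 0.0])
    put("G_2n", "N3", n3_g2n)
    put("A_2b", "H61", n6_a2b + H_LEN * _unit(n3_g2n - n6_a2b))
    put("A_2b", "H62", n6_a2b + H_LEN * np.array([0.0, 0.0, 1.0]))
    n7_a2b = np.array([-15.0, 13.0, 0.0])
    put("A_2b", "N7", n7_a2b)
    n2_g2n = n7_a2b + _don(plan["AG2_N2N7"]) * np.array([1.0, 0.0, 0.0])
    put("G_2n", "N2", n2_g2n)
    put("G_2n", "H21", n2_g2n + H_LEN * _unit(n7_a2b - n2_g2n))
    put("G_2n", "H22", n2_g2n + H_LEN * np.array([0.0, 1.0, 0.0]))
    put("G_1b", "O2'",
        n2_g2n + _don(plan["SB_G1bG2n"]) * np.array([0.0, 0.0, 1.0]),
        needed_for="sugar_base" if plan["SB_G1bG2n"] else None)

    # --- AG3 pair + 4BPh -------------------------------------------------
    n2_g3n = np.array([-15.0, 20.0, 0.0])
    put("G_3n", "N2", n2_g3n)
    n7_a3b = n2_g3n + _don(plan["AG3_N2N7"]) * np.array([-1.0, 0.0, 0.0])
    put("A_3b", "N7", n7_a3b)
    put("G_3n", "H21", n2_g3n + H_LEN * _unit(n7_a3b - n2_g3n))
    op2 = n2_g3n + _don(plan["BPH4_N2"]) * np.array([0.0, -1.0, 0.0])
    put("A_2b", "OP2", op2, needed_for="bph4" if full["bph4"] == "on" else None)
    put("G_3n", "H22", n2_g3n + H_LEN * _unit(op2 - n2_g3n))
    n1_g3n = op2 + _don(plan["BPH4_N1"]) * np.array([0.0, -1.0, 0.0])
    put("G_3n", "N1", n1_g3n,
        needed_for="bph4" if full["bph4"] == "on" else None)
    put("G_3n", "H1", n1_g3n + H_LEN * _unit(op2 - n1_g3n))
    n6_a3b = np.array([-15.0, 24.0, 0.0])
    put("A_3b", "N6", n6_a3b)
    n3_g3n = n6_a3b + _don(plan["AG3_N6N3"]) * np.array([1.0, 0.0, 0.0])
    put("G_3n", "N3", n3_g3n)
    put("A_3b", "H61", n6_a3b + H_LEN * _unit(n3_g3n - n6_a3b))
    put("A_3b", "H62", n6_a3b + H_LEN * np.array([0.0, 0.0, 1.0]))

    # --- sugar-phosphate contact ----------------------------------------
    op1 = np.array([9.0, 8.0, 0.0])
    put("A_L2", "OP1", op1)
    put("A_L3", "O2'", op1 + _don(plan["SP_AL3AL2"]) * np.array([0.0, 1.0, 0.0]),
        needed_for="sugar_phosphate" if plan["SP_AL3AL2"] else None)

    # --- backbone suites -------------------------------------------------
    def suite_chain(role_res, role_prev, start, alpha, gamma,
                    existing=None):
        """Place P/O5'/C5' (+C4'/C3' unless existing) of the suite's 3'
        residue plus the 5' residue's O3', realizing the alpha/gamma bins."""
        if existing is None:
            c3 = np.asarray(start, float)
            c4 = c3 + np.array([0.0, 2.4, 0.0])
            dummy = c3 + np.array([0.0, 0.0, 2.4])
            put(role_res, "C3'", c3)
            put(role_res, "C4'", c4)
        else:
            c3, c4, dummy = existing
        c5 = place_atom_internal(dummy, c3, c4, 2.4, 110.0, -60.0)
        put(role_res, "C5'", c5)
        o5 = place_atom_internal(c3, c4, c5, 2.4, 110.0, gamma)
        put(role_res, "O5'", o5)
        p = place_atom_internal(c4, c5, o5, 2.4, 110.0, 180.0)
        put(role_res, "P", p)
        o3 = place_atom_internal(c5, o5, p, 2.4, 110.0, alpha)
        put(role_prev, "O3'", o3)

    for label, (prev, res) in zip(
            ("suite_A_1n/G_-1n", "suite_G_L1/A_L2", "suite_A_L2/A_L3"),
            (("A_1n", "G_-1n"), ("G_L1", "A_L2"), ("A_L2", "A_L3"))):
        state = full[label]
        bins = _SUITE_NATIVE[label] if state == "native" else _SUITE_CANONICAL
        alpha = _SUITE_TORSIONS[bins[0]]
        gamma = _SUITE_TORSIONS[bins[1]]
        rec(label, "alpha_deg", alpha, 0.0 if bins[0] == "t" else
            (120.0 if alpha > 0 else -120.0))
        rec(label, "gamma_deg", gamma, 0.0 if bins[1] == "t" else
            (120.0 if gamma > 0 else -120.0))
        if res == "A_L2":
            c3p, c4p = atoms[("A_L2", "C3'")], atoms[("A_L2", "C4'")]
            suite_chain(res, prev, None, alpha, gamma,
                        existing=(c3p, c4p, atoms[("A_L2", "C2'")]))
        elif res == "G_-1n":
            suite_chain(res, prev, np.array([-15.0, -14.0, 0.0]),
                        alpha, gamma)
        else:  # A_L3
            suite_chain(res, prev, np.array([17.0, 0.0, 0.0]),
                        alpha, gamma)

    # --- ions ------------------------------------------------------------
    ion_atoms: list[tuple[str, str, str, np.ndarray]] = []
    if "k_ion" in full:
        d_k = {"bound": 2.8, "absent": 5.5}[full["k_ion"]]
        ion_atoms.append(("I", "K", "K", op2 + np.array([d_k, 0.0, 0.0])))
        rec("k_ion", "d(K,OP2)", d_k, 3.5)
    if "mg_ion" in full:
        d_mg = {"inner": 2.8, "outer": 4.15, "unbound": 5.6,
                "absent": None}[full["mg_ion"]]
        if d_mg is not None:
            ion_atoms.append(("I", "MG", "MG",
                              op2 + np.array([-d_mg, 0.0, 0.0])))
            rec("mg_ion", "d(Mg,OP2)", d_mg,
                3.5 if full["mg_ion"] == "inner" else 4.8)

    # --- H-bond margin records ------------------------------------------
    for lab, on in plan.items():
        rec(lab, "heavy_atom_distance", D_ON if on else D_OFF,
            criterion.distance_cutoff)

    # --- deletions -------------------------------------------------------
    for role, name in full["_delete"]:
        key = (role, name)
        if key in required and required[key]:
            raise ConstructionError(
                f"target conflict: deleting {role}({name}) contradicts "
                f"feature {required[key]!r}")
        atoms.pop(key, None)

    # --- assemble Structure ---------------------------------------------
    atom_list: list[Atom] = []
    xyz: list[np.ndarray] = []
    for role, (chain, resnum, resname) in TEMPLATE_RESIDUES.items():
        for (r, name), pos in atoms.items():
            if r == role:
                elem = "P" if name == "P" else name[0]
                atom_list.append(Atom(chain, resnum, resname, name, elem))
                xyz.append(pos)
    for i, (chain, resname, elem, pos) in enumerate(ion_atoms):
        atom_list.append(Atom(chain, 90 + i, resname, resname, elem))
        xyz.append(pos)
    structure = Structure(atom_list, np.asarray(xyz)[None, :, :])

    expected = _expected_states(full, plan)
    return TemplateResult(structure, SYNTHETIC_ANNOTATION, full, report,
                          expected)


def _expected_states(full: dict, plan: dict[str, bool]) -> dict:
    """Classifier outputs the template is built to produce."""
    chi_val = full["chi"] if isinstance(full["chi"], float) \
        else _CHI_VALUES[full["chi"]]
    exp = {
        "si_state": full["si"],
        "aminor_state": full["aminor"],
        "chi_state": "syn" if -90.0 < chi_val < 90.0 else "anti",
        "stacking_partner": full["stacking"],
        "pucker_A_L2": full["pucker"],
        "bph4": full["bph4"] == "on",
        "sugar_phosphate": plan["SP_AL3AL2"],
        "sugar_base": plan["SB_G1bG2n"],
    }
    for label in _SUITE_NATIVE:
        state = full[label]
        bins = _SUITE_NATIVE[label] if state == "native" else _SUITE_CANONICAL
        short = label[len("suite_"):].replace("/", "_")
        exp[f"suite_{short}_alpha"] = bins[0]
        exp[f"suite_{short}_gamma"] = bins[1]
        exp[f"suite_{short}_native"] = state == "native"
    for lab, on in plan.items():
        exp[f"hb_{lab}"] = on
    if "k_ion" in full:
        exp["k_ion"] = full["k_ion"]
    if "mg_ion" in full:
        exp["mg_ion"] = full["mg_ion"]
    return exp


# --------------------------------------------------------------------------
# state-switching simulator
# --------------------------------------------------------------------------

#: stable per-feature stream codes (adding a feature never perturbs others)
FEATURE_CODES = {name: i + 1 for i, name in enumerate(FEATURE_STATES)}

@dataclass
class SyntheticFeature:
    """A categorical feature driven by a stationary Markov chain.

    The transition matrix is (1 - persistence) * ones @ pi + persistence * I:
    row-stochastic, stationary distribution exactly ``stationary``, and
    second eigenvalue equal to ``persistence`` (the per-frame state
    correlation).
    """

    name: str
    states: tuple[str, ...]
    stationary: tuple[float, ...]
    persistence: float = 0.2

    def __post_init__(self):
        if self.name not in FEATURE_STATES:
            raise SyntheticSpecError(f"unknown feature {self.name!r}")
        if len(self.states) != len(self.stationary):
            raise SyntheticSpecError("states/stationary length mismatch")
        for s in self.states:
            if s not in FEATURE_STATES[self.name]:
                raise SyntheticSpecError(
                    f"{self.name}: unknown state {s!r}")
        pi = np.asarray(self.stationary, float)
        if abs(pi.sum() - 1.0) > 1e-9 or (pi < 0).any():
            raise SyntheticSpecError(
                f"{self.name}: stationary must be a distribution")
        if not 0.0 <= self.persistence < 1.0:
            raise SyntheticSpecError("persistence must be in [0, 1)")

    @property
    def transition_matrix(self) -> np.ndarray:
        pi = np.asarray(self.stationary, float)
        k = len(pi)
        return (1.0 - self.persistence) * np.tile(pi, (k, 1)) + \
            self.persistence * np.eye(k)

    def sample_chain(self, n: int, rng: np.random.Generator) -> np.ndarray:
        pi = np.asarray(self.stationary, float)
        cum_pi = np.cumsum(pi)
        tm = self.transition_matrix
        cum_tm = np.cumsum(tm, axis=1)
        draws = rng.random(n)
        out = np.empty(n, dtype=np.int64)
        out[0] = np.searchsorted(cum_pi, draws[0])
        for t in range(1, n):
            out[t] = np.searchsorted(cum_tm[out[t - 1]], draws[t])
        return out


@dataclass(frozen=True)
class CouplingRule:
    """When *trigger* is in one of *trigger_states*, force *target*."""

    trigger: str
    trigger_states: tuple[str, ...]
    target: str
    forced_state: str


@dataclass
class SyntheticSpec:
    """Full specification of a synthetic kink-turn ensemble."""

    n_frames: int = 2000
    n_replicates: int = 5
    seed: int = 0
    noise_sigma: float = 0.1          # A, isotropic per atom
    features: list[SyntheticFeature] = field(default_factory=list)
    coupling: list[CouplingRule] = field(default_factory=list)
    fixed: dict = field(default_factory=dict)   # feature -> fixed state

    def __post_init__(self):
        if self.n_frames < 1 or self.n_replicates < 1:
            raise SyntheticSpecError("frames and replicates must be >= 1")
        if self.noise_sigma < 0:
            raise SyntheticSpecError("noise sigma must be >= 0")
        names = [f.name for f in self.features]
        if len(set(names)) != len(names):
            raise SyntheticSpecError("duplicate feature in spec")
        forced: dict[str, str] = {}
        for rule in self.coupling:
            if rule.trigger not in FEATURE_STATES or \
                    rule.target not in FEATURE_STATES:
                raise SyntheticSpecError(
                    f"coupling rule references unknown feature: {rule}")
            if rule.target in forced and forced[rule.target] != \
                    rule.forced_state:
                raise SyntheticSpecError(
                    f"contradictory coupling rules on {rule.target!r}")
            forced[rule.target] = rule.forced_state


def default_spec(seed: int = 0, n_frames: int = 2000,
                 n_replicates: int = 5,
                 noise_sigma: float = 0.1) -> SyntheticSpec:
    """The default study conditions: every categorical feature switching
    with the stationary fractions below (persistence 0.2), emulating the
    fast reversible exchange the monitored interactions show in MD.
    """
    feats = [
        SyntheticFeature("si", ("native", "non-native", "absent"),
                         (0.7, 0.2, 0.1)),
        SyntheticFeature("aminor", ("AM0", "AMI", "none"), (0.8, 0.15, 0.05)),
        SyntheticFeature("chi", ("syn", "anti"), (0.6, 0.4)),
        SyntheticFeature("stacking", ("A_1n", "G_L1", "none"),
                         (0.5, 0.4, 0.1)),
        SyntheticFeature("pucker", ("C2'-endo", "O4'-endo", "C3'-endo"),
                         (0.5, 0.3, 0.2)),
        SyntheticFeature("suite_A_1n/G_-1n", ("native", "canonical"),
                         (0.7, 0.3)),
        SyntheticFeature("suite_G_L1/A_L2", ("native", "canonical"),
                         (0.3, 0.7)),
        SyntheticFeature("suite_A_L2/A_L3", ("native", "canonical"),
                         (0.9, 0.1)),
        SyntheticFeature("bph4", ("on", "off"), (0.4, 0.6)),
        SyntheticFeature("sugar_phosphate", ("on", "off"), (0.3, 0.7)),
        SyntheticFeature("sugar_base", ("on", "off"), (0.9, 0.1)),
    ]
    return SyntheticSpec(n_frames=n_frames, n_replicates=n_replicates,
                         seed=seed, noise_sigma=noise_sigma, features=feats)


def simulate_ensemble(spec: SyntheticSpec):
    """Simulate the ensembles described by *spec*.

    Returns ``(ensembles, truth)``: one :class:`Ensemble` per replicate
    (frames = template geometry for the frame's state combination plus
    Gaussian coordinate noise) and the ground-truth state table
    (columns: replicate, frame, one column per feature), recorded before
    noise.  Bit-for-bit deterministic under a fixed seed.
    """
    template_cache: dict[tuple, TemplateResult] = {}
    feature_names = [f.name for f in spec.features] + list(spec.fixed)
    ensembles = []
    truth_rows = []
    coords_key_order = None
    for rep in range(1, spec.n_replicates + 1):
        states: dict[str, np.ndarray] = {}
        for feat in spec.features:
            rng = np.random.default_rng(
                np.random.SeedSequence(
                    entropy=int(spec.seed) & 0x7FFFFFFF,
                    spawn_key=(rep, FEATURE_CODES[feat.name])))
            idx = feat.sample_chain(spec.n_frames, rng)
            states[feat.name] = np.asarray(feat.states, object)[idx]
        for name, state in spec.fixed.items():
            states[name] = np.full(spec.n_frames, state, dtype=object)
        # coupling rules (applied in declared order, before geometry)
        for rule in spec.coupling:
            trig = states.get(rule.trigger)
            if trig is None:
                continue
            mask = np.isin(trig, rule.trigger_states)
            if rule.target not in states:
                states[rule.target] = np.full(
                    spec.n_frames,
                    DEFAULT_TARGETS.get(rule.target,
                                        FEATURE_STATES[rule.target][0]),
                    dtype=object)
            states[rule.target][mask] = rule.forced_state
        noise_rng = np.random.default_rng(
            np.random.SeedSequence(entropy=int(spec.seed) & 0x7FFFFFFF,
                                   spawn_key=(rep, 0)))
        frames = []
        active = sorted(states)
        for t in range(spec.n_frames):
            combo = tuple((name, states[name][t]) for name in active)
            tmpl = template_cache.get(combo)
            if tmpl is None:
                tmpl = build_template(dict(combo))
                template_cache[combo] = tmpl
                if coords_key_order is None:
                    coords_key_order = tmpl.structure.atom_table_signature()
                elif tmpl.structure.atom_table_signature() != coords_key_order:
                    raise SyntheticSpecError(
                        "state combinations produce differing atom tables")
            coords = tmpl.structure.coords[0]
            if spec.noise_sigma > 0:
                coords = coords + noise_rng.normal(
                    0.0, spec.noise_sigma, size=coords.shape)
            else:
                coords = coords.copy()
            frames.append(coords)
            row = {"replicate": rep, "frame": t}
            row.update({name: states[name][t] for name in active})
            truth_rows.append(row)
        any_tmpl = next(iter(template_cache.values()))
        st = Structure(any_tmpl.structure.atoms, np.asarray(frames))
        ensembles.append(Ensemble(st, replicate=rep, label="synthetic"))
    truth = pd.DataFrame(truth_rows)
    return ensembles, truth


# --------------------------------------------------------------------------
# recovery report
# --------------------------------------------------------------------------

def recovery_report(estimated: pd.DataFrame, truth: pd.DataFrame,
                    se_multiplier: float = 3.0) -> pd.DataFrame:
    """Compare classified occupancies with the generator's ground truth.

    *estimated* is a per-frame feature table (from
    :func:`kturn.interactions.feature_table`, rows aligned with *truth*).
    For every (feature, state) pair of the ground truth the report lists
    the truth fraction, the classified estimate, the absolute error, the
    binomial standard error sqrt(p (1 - p) / n), and a pass flag
    (|error| <= se_multiplier * SE; for degenerate p in {0, 1} the error
    must be 0).
    """
    if len(estimated) != len(truth):
        raise ValueError("estimated/truth length mismatch")
    est_col = {
        "si": "si_state",
        "aminor": "aminor_state",
        "chi": "chi_state",
        "stacking": "stacking_partner",
        "pucker": "pucker_A_L2",
        "suite_A_1n/G_-1n": "suite_A_1n_G_-1n_native",
        "suite_G_L1/A_L2": "suite_G_L1_A_L2_native",
        "suite_A_L2/A_L3": "suite_A_L2_A_L3_native",
        "bph4": "bph4",
        "sugar_phosphate": "sugar_phosphate",
        "sugar_base": "sugar_base",
    }
    bool_map = {"bph4": {"on": True, "off": False},
                "sugar_phosphate": {"on": True, "off": False},
                "sugar_base": {"on": True, "off": False},
                "suite_A_1n/G_-1n": {"native": True, "canonical": False},
                "suite_G_L1/A_L2": {"native": True, "canonical": False},
                "suite_A_L2/A_L3": {"native": True, "canonical": False}}
    rows = []
    n = len(truth)
    for feature in truth.columns:
        if feature in ("replicate", "frame"):
            continue
        col = est_col.get(feature)
        if col is None or col not in estimated.columns:
            raise ValueError(f"no classified column for feature {feature!r}")
        tvals = truth[feature].to_numpy()
        evals = estimated[col].to_numpy()
        for state in pd.unique(tvals):
            p_truth = float(np.mean(tvals == state))
            target = bool_map.get(feature, {}).get(state, state)
            p_est = float(np.mean(evals == target))
            err = abs(p_est - p_truth)
            se = math.sqrt(p_truth * (1.0 - p_truth) / n)
            ok = err <= se_multiplier * se if se > 0 else err == 0.0
            rows.append({"feature": feature, "state": state,
                         "truth_fraction": p_truth, "estimate": p_est,
                         "abs_error": err, "binomial_se": se,
                         "passed": bool(ok), "n": n})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# repertoire enumeration
# --------------------------------------------------------------------------

def enumerate_state_combinations():
    """Yield target dicts covering the supported state repertoire.

    The enumeration is the documented acceptance surface for zero-noise
    oracle equivalence: the full cross of the five structural categoricals
    (SI x A-minor x chi x stacking x pucker), the full cross of the three
    suite states with the three contact booleans, individual toggles of
    every overridable H-bond, the 4BPh either-or variants, and the ion
    placements.
    """
    cats = ("si", "aminor", "chi", "stacking", "pucker")
    for combo in itertools.product(*(FEATURE_STATES[c] for c in cats)):
        yield dict(zip(cats, combo))
    flex = ("suite_A_1n/G_-1n", "suite_G_L1/A_L2", "suite_A_L2/A_L3",
            "bph4", "sugar_phosphate", "sugar_base")
    for combo in itertools.product(*(FEATURE_STATES[f] for f in flex)):
        yield dict(zip(flex, combo))
    for lab in AG_LABELS + GC_LABELS + ("AM0_B", "AMI_B"):
        yield {lab: "off"}
    # 4BPh either-or: N1 only, N2 only, both
    yield {"bph4": "on", "BPH4_N1": "on", "BPH4_N2": "off"}
    yield {"bph4": "on", "BPH4_N1": "off", "BPH4_N2": "on"}
    yield {"bph4": "on", "BPH4_N1": "on", "BPH4_N2": "on"}
    for state in ("bound", "absent"):
        yield {"k_ion": state}
    for state in ("inner", "outer", "unbound"):
        yield {"mg_ion": state}
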