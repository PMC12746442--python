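"""Per-frame classification of the characteristic kink-turn interactions.

The classifiers implement the geometric criteria used to monitor Kt-7
integrity in MD ensembles:

* direct H-bond: heavy-atom distance < 4.0 A and donor-H-acceptor angle
  > 120 deg, with the angle condition waived for H-bonds involving
  O2'-groups (their orientational flexibility makes the angle test produce
  false negatives);
* the signature interaction (SI) G_L1(O2')-A_1n(N1), with the alternative
  G_L1(O2')-A_1n(N6) contact scored as the *non-native* SI;
* A-minor type 0 (AM0_A/AM0_B bonds) vs type I (AMI_A/AMI_B/AMI_C), with
  the water-insertion rule: A-minor I counts as formed when AMI_A and AMI_C
  hold even if AMI_B is broken (transient water bridge);
* the three tHS AG base pairs of the NC-stem and the bulge-proximal
  Watson-Crick GC pair of the C-stem;
* the 4BPh base-phosphate contact A_2b(OP2)-G_3n(N1/N2), either-or;
* the sugar-phosphate A_L3(O2')-A_L2(OP1) and sugar-base G_1b(O2')-G_2n(N2)
  contacts;
* chi glycosidic state of A_L2 (syn iff chi in (-90, +90));
* A_L2 stacking partner via endocyclic-N geometric centers
  (cutoffs 4.0 A vs A_1n, 4.5 A vs G_L1);
* alpha/gamma suite bins for the three noncanonical backbone suites
  (native combinations g+/t, g+/g-, g+/g+);
* sugar pseudorotation class of monitored residues;
* K+/Na+ contacts (3.5 A) and Mg2+ inner/outer shells (3.5 / 4.8 A).

Missing atoms never yield silent defaults: every classifier reports the
``Unresolvable`` sentinel for what it cannot measure.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .geometry import (
    RING_NITROGENS,
    classify_gauche,
    dihedral,
    pseudorotation,
    ring_center,
)
from .structure_io import (
    Ensemble,
    KinkTurnAnnotation,
    Structure,
    Unresolvable,
    UNRESOLVABLE,
)

__all__ = [
    "HBondCriterion",
    "HBondSpec",
    "HBondResult",
    "CATALOGUE",
    "FeatureVector",
    "FrameView",
    "MissingHydrogenError",
    "hbond_present",
    "classify_si",
    "classify_aminor",
    "basepair_flags",
    "detect_bph4",
    "detect_sugar_phosphate",
    "detect_sugar_base",
    "classify_chi",
    "classify_stacking",
    "classify_suites",
    "ion_contacts",
    "feature_vector",
    "feature_table",
]


class MissingHydrogenError(ValueError):
    """Angle criterion required but the donor has no hydrogens in the file."""


# --------------------------------------------------------------------------
# criterion / catalogue
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class HBondCriterion:
    """H-bond presence criterion (heavy-atom distance + D-H-A angle)."""

    distance_cutoff: float = 4.0   # Angstrom, heavy atoms
    angle_cutoff: float = 120.0    # degrees, donor-hydrogen-acceptor
    #: accept distance-only evaluation when hydrogens are absent
    #: (crystal structures); a warning is emitted per evaluation set.
    distance_only_fallback: bool = False

    def __post_init__(self):
        if self.distance_cutoff <= 0 or self.angle_cutoff <= 0:
            raise ValueError("cutoffs must be positive")


@dataclass(frozen=True)
class HBondSpec:
    """One catalogued H-bond: donor role/heavy atom and acceptor role/atom."""

    label: str
    donor_role: str
    donor_atom: str
    acceptor_role: str
    acceptor_atom: str

    @property
    def angle_exempt(self) -> bool:
        """Either partner an O2'-group atom => angle condition waived."""
        return self.donor_atom == "O2'" or self.acceptor_atom == "O2'"


def _spec(label, donor, acceptor) -> HBondSpec:
    dr, da = donor
    ar, aa = acceptor
    return HBondSpec(label, dr, da, ar, aa)


#: the full monitored H-bond catalogue
CATALOGUE: dict[str, HBondSpec] = {
    s.label: s
    for s in [
        _spec("SI_native", ("G_L1", "O2'"), ("A_1n", "N1")),
        _spec("SI_nonnative", ("G_L1", "O2'"), ("A_1n", "N6")),
        _spec("AM0_A", ("G_-1n", "O2'"), ("A_2b", "N3")),
        _spec("AM0_B", ("G_-1n", "O2'"), ("A_2b", "O2'")),
        _spec("AMI_A", ("G_-1n", "O2'"), ("A_2b", "N1")),
        _spec("AMI_B", ("C_-1b", "O2'"), ("A_2b", "O2'")),
        _spec("AMI_C", ("G_-1n", "N2"), ("A_2b", "N3")),
        _spec("AG1_N6N3", ("A_1n", "N6"), ("G_1b", "N3")),
        _spec("AG1_N2N7", ("G_1b", "N2"), ("A_1n", "N7")),
        _spec("AG2_N6N3", ("A_2b", "N6"), ("G_2n", "N3")),
        _spec("AG2_N2N7", ("G_2n", "N2"), ("A_2b", "N7")),
        _spec("AG3_N6N3", ("A_3b", "N6"), ("G_3n", "N3")),
        _spec("AG3_N2N7", ("G_3n", "N2"), ("A_3b", "N7")),
        _spec("GC_O6N4", ("C_-1b", "N4"), ("G_-1n", "O6")),
        _spec("GC_N1N3", ("G_-1n", "N1"), ("C_-1b", "N3")),
        _spec("GC_O2N2", ("G_-1n", "N2"), ("C_-1b", "O2")),
        _spec("BPH4_N1", ("G_3n", "N1"), ("A_2b", "OP2")),
        _spec("BPH4_N2", ("G_3n", "N2"), ("A_2b", "OP2")),
        _spec("SP_AL3AL2", ("A_L3", "O2'"), ("A_L2", "OP1")),
        _spec("SB_G1bG2n", ("G_1b", "O2'"), ("G_2n", "N2")),
    ]
}

AG_LABELS = ("AG1_N6N3", "AG1_N2N7", "AG2_N6N3",
             "AG2_N2N7", "AG3_N6N3", "AG3_N2N7")
GC_LABELS = ("GC_O6N4", "GC_N1N3", "GC_O2N2")

#: donor heavy atom -> candidate hydrogen names, keyed by base letter
#: ('*' matches any base, for the ribose O2' hydroxyl)
DONOR_HYDROGENS: dict[tuple[str, str], tuple[str, ...]] = {
    ("A", "N6"): ("H61", "H62"),
    ("G", "N1"): ("H1",),
    ("G", "N2"): ("H21", "H22"),
    ("C", "N4"): ("H41", "H42"),
    ("U", "N3"): ("H3",),
    ("*", "O2'"): ("HO2'",),
}

_BASE_ALIASES = {
    "A": "A", "RA": "A", "ADE": "A", "DA": "A",
    "G": "G", "RG": "G", "GUA": "G", "DG": "G",
    "C": "C", "RC": "C", "CYT": "C", "DC": "C",
    "U": "U", "RU": "U", "URA": "U", "URI": "U",
}

PURINES = ("A", "G")

#: suite label -> (5' residue role, 3' residue role, native (alpha, gamma))
SUITE_DEFS = (
    ("A_1n/G_-1n", "A_1n", "G_-1n", ("g+", "t")),
    ("G_L1/A_L2", "G_L1", "A_L2", ("g+", "g-")),
    ("A_L2/A_L3", "A_L2", "A_L3", ("g+", "g+")),
)

DEFAULT_PUCKER_ROLES = ("A_L2",)
DEFAULT_ION_ACCEPTORS = (("A_2b", "OP2"), ("A_L2", "OP1"))

MONOVALENT_CUTOFF = 3.5   # Angstrom, K+/Na+
MG_INNER_CUTOFF = 3.5     # Angstrom
MG_OUTER_CUTOFF = 4.8     # Angstrom

_MONOVALENT_ELEMENTS = {"K", "NA"}
_MG_ELEMENTS = {"MG"}
_ION_RESNAMES = {"K": "K", "K+": "K", "NA": "NA", "NA+": "NA",
                 "MG": "MG", "MG2": "MG"}

#: pairs separated by more than this are suspicious for exported frames of
#: a compact solute (coordinates are assumed already imaged)
PAIR_DISTANCE_GUARD = 50.0


def base_letter(resname: str) -> str | None:
    """Canonical one-letter base for a residue name, or None."""
    return _BASE_ALIASES.get(resname.strip().upper())


# --------------------------------------------------------------------------
# frame access
# --------------------------------------------------------------------------

class FrameView:
    """Positions of one frame addressed by (kink-turn role, atom name).

    Resolution of (role, atom) -> atom index is cached per atom table so
    that classifying many frames of one ensemble costs dictionary lookups
    only.
    """

    def __init__(self, structure: Structure, annotation: KinkTurnAnnotation,
                 frame: int = 0, coords: np.ndarray | None = None):
        self.structure = structure
        self.annotation = annotation
        self.coords = structure.coords[frame] if coords is None else coords
        cache = getattr(structure, "_role_atom_cache", None)
        if cache is None or cache[0] is not annotation:
            cache = (annotation, {})
            structure._role_atom_cache = cache
        self._cache = cache[1]

    def index(self, role: str, atom: str):
        key = (role, atom)
        idx = self._cache.get(key)
        if idx is None:
            if role not in self.annotation:
                idx = Unresolvable(f"role {role!r} absent from annotation")
            else:
                chain, resnum = self.annotation.residue(role)
                idx = self.structure.atom_index(chain, resnum, atom)
            self._cache[key] = idx
        return idx

    def pos(self, role: str, atom: str):
        idx = self.index(role, atom)
        if isinstance(idx, Unresolvable):
            return idx
        return self.coords[idx]

    def resname(self, role: str):
        idx = self.index(role, "C1'")
        if isinstance(idx, Unresolvable):
            # fall back to any atom of the residue
            if role not in self.annotation:
                return UNRESOLVABLE
            chain, resnum = self.annotation.residue(role)
            for a in self.structure.atoms:
                if a.chain == chain and a.resnum == resnum:
                    return a.resname
            return UNRESOLVABLE
        return self.structure.atoms[idx].resname


def _dist(p, q) -> float:
    return float(np.linalg.norm(np.asarray(p) - np.asarray(q)))


# --------------------------------------------------------------------------
# H-bond evaluation
# --------------------------------------------------------------------------

@dataclass
class HBondResult:
    present: object            # bool or Unresolvable
    distance: float = math.nan
    best_angle: float = math.nan

    def __bool__(self):
        return self.present is True


def _donor_hydrogens(view: FrameView, spec: HBondSpec):
    base = base_letter(view.resname(spec.donor_role) or "")
    names = DONOR_HYDROGENS.get((base, spec.donor_atom)) or \
        DONOR_HYDROGENS.get(("*", spec.donor_atom), ())
    out = []
    for h in names:
        p = view.pos(spec.donor_role, h)
        if not isinstance(p, Unresolvable):
            out.append(p)
    return out


def hbond_present(view: FrameView, spec: HBondSpec,
                  criterion: HBondCriterion = HBondCriterion()) -> HBondResult:
    """Evaluate one catalogued H-bond on one frame.

    Present iff heavy-atom distance < cutoff and (angle-exempt, or the best
    donor-H-acceptor angle over the donor's hydrogens exceeds the angle
    cutoff).  Missing heavy atoms give the Unresolvable sentinel; a needed
    but absent hydrogen raises MissingHydrogenError unless the criterion's
    distance-only fallback is enabled.
    """
    dp = view.pos(spec.donor_role, spec.donor_atom)
    ap = view.pos(spec.acceptor_role, spec.acceptor_atom)
    if isinstance(dp, Unresolvable):
        return HBondResult(Unresolvable(f"{spec.label}: donor {dp.reason}"))
    if isinstance(ap, Unresolvable):
        return HBondResult(Unresolvable(f"{spec.label}: acceptor {ap.reason}"))
    d = _dist(dp, ap)
    if d > PAIR_DISTANCE_GUARD:
        warnings.warn(
            f"monitored pair {spec.label} separated by {d:.1f} A; "
            "coordinates may not be whole/imaged", stacklevel=2)
    if d >= criterion.distance_cutoff:
        return HBondResult(False, d)
    if spec.angle_exempt:
        return HBondResult(True, d)
    hydrogens = _donor_hydrogens(view, spec)
    if not hydrogens:
        if criterion.distance_only_fallback:
            warnings.warn(
                f"{spec.label}: donor hydrogens absent, distance-only "
                "evaluation", stacklevel=2)
            return HBondResult(True, d)
        raise MissingHydrogenError(
            f"{spec.label}: donor {spec.donor_role}({spec.donor_atom}) has "
            "no hydrogens; enable distance_only_fallback for H-free input")
    best = max(_angle_at(dp, h, ap) for h in hydrogens)
    return HBondResult(best > criterion.angle_cutoff, d, best)


def _angle_at(a, h, b) -> float:
    u = np.asarray(a) - np.asarray(h)
    v = np.asarray(b) - np.asarray(h)
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu < 1e-10 or nv < 1e-10:
        return 0.0
    c = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(c)))


# --------------------------------------------------------------------------
# named classifiers
# --------------------------------------------------------------------------

@dataclass
class SIResult:
    state: object                # 'native' | 'non-native' | 'absent' | sentinel
    d_native: float = math.nan
    d_nonnative: float = math.nan


def classify_si(view: FrameView,
                criterion: HBondCriterion = HBondCriterion()) -> SIResult:
    """Signature-interaction state of the frame.

    Both SI variants involve the G_L1 O2' group, so both are distance-only
    under the O2' angle exemption.  If both heavy-atom distances pass the
    cutoff, the shorter one wins (proxy for the occupied arrangement).
    """
    rn = hbond_present(view, CATALOGUE["SI_native"], criterion)
    rnn = hbond_present(view, CATALOGUE["SI_nonnative"], criterion)
    if isinstance(rn.present, Unresolvable) or \
            isinstance(rnn.present, Unresolvable):
        bad = rn.present if isinstance(rn.present, Unresolvable) else rnn.present
        return SIResult(Unresolvable(bad.reason), rn.distance, rnn.distance)
    if rn.present and rnn.present:
        state = "native" if rn.distance <= rnn.distance else "non-native"
    elif rn.present:
        state = "native"
    elif rnn.present:
        state = "non-native"
    else:
        state = "absent"
    return SIResult(state, rn.distance, rnn.distance)


@dataclass
class AMinorResult:
    state: object                       # 'AM0' | 'AMI' | 'none' | sentinel
    flags: dict = field(default_factory=dict)


_AMINOR_LABELS = ("AM0_A", "AM0_B", "AMI_A", "AMI_B", "AMI_C")


def classify_aminor(view: FrameView,
                    criterion: HBondCriterion = HBondCriterion()) -> AMinorResult:
    """A-minor state: AMI if AMI_A and AMI_C hold (AMI_B optional under the
    water-insertion rule), else AM0 if AM0_A holds, else none.

    AM0 presence is keyed to AM0_A alone; AM0_B is reported as an auxiliary
    flag and is never decisive.
    """
    flags = {lab: hbond_present(view, CATALOGUE[lab], criterion)
             for lab in _AMINOR_LABELS}
    decisive = ("AM0_A", "AMI_A", "AMI_C")
    for lab in decisive:
        if isinstance(flags[lab].present, Unresolvable):
            return AMinorResult(Unresolvable(flags[lab].present.reason),
                                {k: v.present for k, v in flags.items()})
    if flags["AMI_A"].present and flags["AMI_C"].present:
        state = "AMI"
    elif flags["AM0_A"].present:
        state = "AM0"
    else:
        state = "none"
    return AMinorResult(state, {k: v.present for k, v in flags.items()})


def basepair_flags(view: FrameView,
                   criterion: HBondCriterion = HBondCriterion()) -> dict:
    """Flags for the six AG (NC-stem) and three GC (C-stem) H-bonds."""
    return {lab: hbond_present(view, CATALOGUE[lab], criterion).present
            for lab in AG_LABELS + GC_LABELS}


def detect_bph4(view: FrameView,
                criterion: HBondCriterion = HBondCriterion()):
    """4BPh contact: either A_2b(OP2)-G_3n(N1) or -G_3n(N2), or both."""
    r1 = hbond_present(view, CATALOGUE["BPH4_N1"], criterion)
    r2 = hbond_present(view, CATALOGUE["BPH4_N2"], criterion)
    if isinstance(r1.present, Unresolvable) and \
            isinstance(r2.present, Unresolvable):
        return r1.present
    vals = [r.present for r in (r1, r2)
            if not isinstance(r.present, Unresolvable)]
    return any(vals)


def detect_sugar_phosphate(view: FrameView,
                           criterion: HBondCriterion = HBondCriterion()):
    """A_L3(O2')-A_L2(OP1) sugar-phosphate contact (distance-only)."""
    return hbond_present(view, CATALOGUE["SP_AL3AL2"], criterion).present


def detect_sugar_base(view: FrameView,
                      criterion: HBondCriterion = HBondCriterion()):
    """G_1b(O2')-G_2n(N2) sugar-base contact (distance-only)."""
    return hbond_present(view, CATALOGUE["SB_G1bG2n"], criterion).present


@dataclass
class ChiResult:
    value: object          # degrees or sentinel
    state: object          # 'syn' | 'anti' | sentinel


def classify_chi(view: FrameView, role: str = "A_L2") -> ChiResult:
    """Glycosidic torsion chi and its syn/anti state.

    syn iff chi lies in the open interval (-90, +90); the boundary values
    +-90 classify as anti (a closed convention is needed for determinism).
    Quadruple: O4'-C1'-N9-C4 for purines, O4'-C1'-N1-C2 for pyrimidines.
    """
    base = base_letter(view.resname(role) or "")
    if base is None:
        return ChiResult(UNRESOLVABLE, Unresolvable(f"unknown base for {role}"))
    quad = ("O4'", "C1'", "N9", "C4") if base in PURINES else \
        ("O4'", "C1'", "N1", "C2")
    pts = [view.pos(role, a) for a in quad]
    for p in pts:
        if isinstance(p, Unresolvable):
            return ChiResult(UNRESOLVABLE, p)
    chi = dihedral(*pts)
    return ChiResult(chi, "syn" if -90.0 < chi < 90.0 else "anti")


@dataclass
class StackingResult:
    partner: object              # 'A_1n' | 'G_L1' | 'none' | sentinel
    d_a1n: float = math.nan
    d_gl1: float = math.nan


STACK_CUTOFFS = {"A_1n": 4.0, "G_L1": 4.5}


def _endo_n_center(view: FrameView, role: str):
    base = base_letter(view.resname(role) or "")
    if base is None:
        return Unresolvable(f"unknown base for {role}")
    names = RING_NITROGENS["purine" if base in PURINES else "pyrimidine"]
    pts = []
    for n in names:
        p = view.pos(role, n)
        if isinstance(p, Unresolvable):
            return p
        pts.append(p)
    return ring_center(pts)


def classify_stacking(view: FrameView) -> StackingResult:
    """Stacking partner of A_L2 via endocyclic-N geometric centers.

    d(A_L2, A_1n) < 4.0 A and d(A_L2, G_L1) < 4.5 A define the candidate
    stacks; when both pass, the smaller distance/cutoff ratio wins (raw
    distance would bias toward the looser cutoff).
    """
    c_l2 = _endo_n_center(view, "A_L2")
    c_1n = _endo_n_center(view, "A_1n")
    c_l1 = _endo_n_center(view, "G_L1")
    for c in (c_l2, c_1n, c_l1):
        if isinstance(c, Unresolvable):
            return StackingResult(c)
    d1 = _dist(c_l2, c_1n)
    d2 = _dist(c_l2, c_l1)
    pass1 = d1 < STACK_CUTOFFS["A_1n"]
    pass2 = d2 < STACK_CUTOFFS["G_L1"]
    if pass1 and pass2:
        partner = "A_1n" if d1 / STACK_CUTOFFS["A_1n"] <= \
            d2 / STACK_CUTOFFS["G_L1"] else "G_L1"
    elif pass1:
        partner = "A_1n"
    elif pass2:
        partner = "G_L1"
    else:
        partner = "none"
    return StackingResult(partner, d1, d2)


@dataclass
class SuiteResult:
    alpha: object               # degrees or sentinel
    gamma: object
    alpha_bin: object
    gamma_bin: object
    native: object              # bool or sentinel


def classify_suites(view: FrameView) -> dict[str, SuiteResult]:
    """alpha/gamma gauche bins of the three monitored backbone suites.

    alpha and gamma are measured on the 3' residue of each suite
    (alpha: O3'(i-1)-P-O5'-C5'; gamma: O5'-C5'-C4'-C3'); the annotation's
    ``suites`` section may override the quadruples.  The native flag is
    true iff (alpha bin, gamma bin) equals the suite's native combination.
    """
    out: dict[str, SuiteResult] = {}
    overrides = view.annotation.suite_overrides or {}
    for label, prev, res, native_combo in SUITE_DEFS:
        ov = overrides.get(label, {})
        alpha_quad = ov.get("alpha") or [(prev, "O3'"), (res, "P"),
                                         (res, "O5'"), (res, "C5'")]
        gamma_quad = ov.get("gamma") or [(res, "O5'"), (res, "C5'"),
                                         (res, "C4'"), (res, "C3'")]
        vals = []
        sentinel = None
        for quad in (alpha_quad, gamma_quad):
            pts = []
            for r, a in quad:
                p = view.pos(r, a)
                if isinstance(p, Unresolvable):
                    sentinel = p
                    break
                pts.append(p)
            if sentinel is not None:
                break
            vals.append(dihedral(*pts))
        if sentinel is not None:
            out[label] = SuiteResult(sentinel, sentinel, sentinel,
                                     sentinel, sentinel)
            continue
        alpha, gamma = vals
        bins = (classify_gauche(alpha), classify_gauche(gamma))
        out[label] = SuiteResult(alpha, gamma, bins[0], bins[1],
                                 bins == tuple(native_combo))
    return out


@dataclass
class IonContactRecord:
    monovalent_bound: object       # bool
    d_monovalent: float = math.nan
    mg_shell: object = "unbound"   # 'inner' | 'outer' | 'unbound'
    d_mg: float = math.nan


def _ion_positions(view: FrameView):
    mono, mg = [], []
    for i, a in enumerate(view.structure.atoms):
        elem = (a.element or "").upper()
        tag = _ION_RESNAMES.get(a.resname.upper()) or \
            _ION_RESNAMES.get(a.name.upper()) or \
            (elem if elem in _MONOVALENT_ELEMENTS | _MG_ELEMENTS else None)
        if tag in ("K", "NA"):
            mono.append(view.coords[i])
        elif tag == "MG":
            mg.append(view.coords[i])
    return mono, mg


def ion_contacts(view: FrameView,
                 acceptors=DEFAULT_ION_ACCEPTORS,
                 monovalent_cutoff: float = MONOVALENT_CUTOFF,
                 mg_inner: float = MG_INNER_CUTOFF,
                 mg_outer: float = MG_OUTER_CUTOFF) -> dict:
    """Per-acceptor ion contacts: monovalent bound within 3.5 A; Mg2+ shell
    inner (< 3.5), outer ([3.5, 4.8)) or unbound.  No ions => all unbound.
    """
    mono, mg = _ion_positions(view)
    out = {}
    for role, atom in acceptors:
        p = view.pos(role, atom)
        key = f"{role}({atom})"
        if isinstance(p, Unresolvable):
            out[key] = IonContactRecord(p, mg_shell=p)
            continue
        dm = min((_dist(p, q) for q in mono), default=math.inf)
        dg = min((_dist(p, q) for q in mg), default=math.inf)
        if dg < mg_inner:
            shell = "inner"
        elif dg < mg_outer:
            shell = "outer"
        else:
            shell = "unbound"
        out[key] = IonContactRecord(dm < monovalent_cutoff, dm, shell, dg)
    return out


# --------------------------------------------------------------------------
# aggregate feature vector
# --------------------------------------------------------------------------

@dataclass
class FeatureVector:
    """All monitored kink-turn features of one frame."""

    si_state: object
    si_d_native: float
    si_d_nonnative: float
    aminor_state: object
    hbonds: dict
    chi_value: object
    chi_state: object
    stacking_partner: object
    stack_d_a1n: float
    stack_d_gl1: float
    pucker: dict
    suites: dict
    bph4: object
    sugar_phosphate: object
    sugar_base: object
    ions: dict

    def to_row(self) -> dict:
        """Flatten into one serializable record (sentinels -> 'unresolvable')."""
        def v(x):
            if isinstance(x, Unresolvable):
                return "unresolvable"
            if isinstance(x, (np.floating, np.bool_)):
                return x.item()
            return x

        row = {
            "si_state": v(self.si_state),
            "si_d_native": v(self.si_d_native),
            "si_d_nonnative": v(self.si_d_nonnative),
            "aminor_state": v(self.aminor_state),
            "chi_value": v(self.chi_value),
            "chi_state": v(self.chi_state),
            "stacking_partner": v(self.stacking_partner),
            "stack_d_a1n": v(self.stack_d_a1n),
            "stack_d_gl1": v(self.stack_d_gl1),
            "bph4": v(self.bph4),
            "sugar_phosphate": v(self.sugar_phosphate),
            "sugar_base": v(self.sugar_base),
        }
        for lab, flag in self.hbonds.items():
            row[f"hb_{lab}"] = v(flag)
        for role, cls in self.pucker.items():
            row[f"pucker_{role}"] = v(cls)
        for lab, s in self.suites.items():
            short = lab.replace("/", "_")
            row[f"suite_{short}_alpha"] = v(s.alpha_bin)
            row[f"suite_{short}_gamma"] = v(s.gamma_bin)
            row[f"suite_{short}_native"] = v(s.native)
        for key, rec in self.ions.items():
            row[f"ion_mono_{key}"] = v(rec.monovalent_bound)
            row[f"ion_mg_{key}"] = v(rec.mg_shell)
        return row


def _classify_pucker(view: FrameView, role: str):
    ring = ("O4'", "C1'", "C2'", "C3'", "C4'")
    pts = []
    for a in ring:
        p = view.pos(role, a)
        if isinstance(p, Unresolvable):
            return p
        pts.append(p)
    o4, c1, c2, c3, c4 = pts
    nu0 = dihedral(c4, o4, c1, c2)
    nu1 = dihedral(o4, c1, c2, c3)
    nu2 = dihedral(c1, c2, c3, c4)
    nu3 = dihedral(c2, c3, c4, o4)
    nu4 = dihedral(c3, c4, o4, c1)
    sp = pseudorotation(nu0, nu1, nu2, nu3, nu4)
    if sp.pucker_class is None:
        return Unresolvable("flat sugar ring")
    return sp.pucker_class


def feature_vector(view_or_structure, annotation=None,
                   criterion: HBondCriterion = HBondCriterion(),
                   pucker_roles=DEFAULT_PUCKER_ROLES,
                   ion_acceptors=DEFAULT_ION_ACCEPTORS,
                   frame: int = 0) -> FeatureVector:
    """Evaluate every classifier on one frame.

    Accepts either a FrameView or (Structure, annotation, frame).  Partial
    annotations degrade gracefully: missing atoms propagate as sentinels,
    never as aborts.
    """
    if isinstance(view_or_structure, FrameView):
        view = view_or_structure
    else:
        view = FrameView(view_or_structure, annotation, frame)
    si = classify_si(view, criterion)
    am = classify_aminor(view, criterion)
    bp = basepair_flags(view, criterion)
    hbonds = dict(am.flags)
    hbonds.update(bp)
    for lab in ("SI_native", "SI_nonnative", "BPH4_N1", "BPH4_N2",
                "SP_AL3AL2", "SB_G1bG2n"):
        hbonds[lab] = hbond_present(view, CATALOGUE[lab], criterion).present
    chi = classify_chi(view)
    stack = classify_stacking(view)
    suites = classify_suites(view)
    pucker = {role: _classify_pucker(view, role) for role in pucker_roles}
    return FeatureVector(
        si_state=si.state,
        si_d_native=si.d_native,
        si_d_nonnative=si.d_nonnative,
        aminor_state=am.state,
        hbonds=hbonds,
        chi_value=chi.value,
        chi_state=chi.state,
        stacking_partner=stack.partner,
        stack_d_a1n=stack.d_a1n,
        stack_d_gl1=stack.d_gl1,
        pucker=pucker,
        suites=suites,
        bph4=detect_bph4(view, criterion),
        sugar_phosphate=detect_sugar_phosphate(view, criterion),
        sugar_base=detect_sugar_base(view, criterion),
        ions=ion_contacts(view, ion_acceptors),
    )


def feature_table(ensemble: Ensemble, annotation: KinkTurnAnnotation,
                  criterion: HBondCriterion = HBondCriterion(),
                  pucker_roles=DEFAULT_PUCKER_ROLES,
                  ion_acceptors=DEFAULT_ION_ACCEPTORS):
    """Classify every frame of an ensemble into a pandas DataFrame.

    One row per frame with 'replicate' and 'frame' columns prepended.
    """
    import pandas as pd

    st = ensemble.structure
    rows = []
    for i in range(ensemble.n_frames):
        view = FrameView(st, annotation, frame=i)
        fv = feature_vector(view, criterion=criterion,
                            pucker_roles=pucker_roles,
                            ion_acceptors=ion_acceptors)
        row = {"replicate": ensemble.replicate, "frame": i}
        row.update(fv.to_row())
        rows.append(row)
    return pd.DataFrame(rows)
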