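"""Reading/writing structures and ensembles, atom-name normalization,
kink-turn role annotation, and the simulation manifest.

Multi-model PDB is the trajectory interchange format: MD frames exported as
MODEL/ENDMDL blocks.  Parsing and serialization are delegated to gemmi; this
module adds atom-name dialect normalization (prime/star synonyms, OP1/O1P),
the role-label mapping, and consistency validation.
"""

from __future__ import annotations

import io as _io
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd
import yaml

__all__ = [
    "Unresolvable",
    "UNRESOLVABLE",
    "Structure",
    "Ensemble",
    "KinkTurnAnnotation",
    "SimulationManifest",
    "normalize_atom_name",
    "read_structure",
    "read_ensemble",
    "write_ensemble",
    "load_annotation",
    "resolve_atom",
    "load_manifest",
    "summarize_manifest",
    "packaged_manifest_path",
    "FormatError",
    "ConsistencyError",
    "AnnotationError",
]


class FormatError(ValueError):
    """File parsed but is not a usable structure (e.g. zero atoms)."""


class ConsistencyError(ValueError):
    """Atom tables differ where they must agree."""


class AnnotationError(ValueError):
    """Invalid kink-turn role annotation."""


class Unresolvable:
    """Explicit sentinel for an atom/feature that cannot be resolved.

    Carries a human-readable reason; truthiness is False so classifier
    results can be guarded with plain ``if``.
    """

    __slots__ = ("reason",)

    def __init__(self, reason: str = ""):
        self.reason = reason

    def __bool__(self):
        return False

    def __repr__(self):
        return f"Unresolvable({self.reason!r})"

    def __eq__(self, other):
        return isinstance(other, Unresolvable)

    def __hash__(self):
        return hash("Unresolvable")


#: shared sentinel for the common case
UNRESOLVABLE = Unresolvable("unresolvable")


# ---------------------------------------------------------------------------
# atom-name normalization
# ---------------------------------------------------------------------------

# Canonical names use the ASCII apostrophe for primes.  The synonym table is
# explicit data: inputs span AMBER/CHARMM/Tinker PDB dialects which disagree
# on star-vs-prime and on phosphate-oxygen naming.
ATOM_SYNONYMS = {
    "O1P": "OP1",
    "O2P": "OP2",
    "O3P": "OP3",
    "HO2'": "HO2'",
    "HO'2": "HO2'",
    "2HO'": "HO2'",
    "H2''": "H2''",
    "HO5'": "HO5'",
    "HO3'": "HO3'",
}


def normalize_atom_name(name: str) -> str:
    """Map a PDB atom name to its canonical form (idempotent).

    Stars become primes (O2* -> O2'), then the explicit synonym table is
    applied (O1P -> OP1, HO'2 -> HO2', ...).
    """
    n = name.strip().replace("*", "'")
    return ATOM_SYNONYMS.get(n, n)


@dataclass(frozen=True)
class Atom:
    chain: str
    resnum: int
    resname: str
    name: str
    element: str


class Structure:
    """Atom table plus per-model coordinates.

    ``coords`` has shape (n_models, n_atoms, 3) in Angstrom; the atom table
    is shared by all models.  (chain, resnum, atom name) is unique within a
    model.
    """

    def __init__(self, atoms: list[Atom], coords: np.ndarray):
        coords = np.asarray(coords, dtype=float)
        if coords.ndim != 3 or coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_models, n_atoms, 3)")
        if coords.shape[1] != len(atoms):
            raise ValueError("coords/atom-table length mismatch")
        if not np.all(np.isfinite(coords)):
            raise ValueError("non-finite coordinates")
        self.atoms = list(atoms)
        self.coords = coords
        self._index: dict[tuple[str, int, str], int] = {}
        for i, at in enumerate(self.atoms):
            key = (at.chain, at.resnum, at.name)
            if key in self._index:
                raise ConsistencyError(f"duplicate atom {key}")
            self._index[key] = i
        if not self.atoms:
            raise FormatError("structure contains no atoms")

    @property
    def n_models(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def atom_index(self, chain: str, resnum: int, name: str):
        """Index of the named atom, or UNRESOLVABLE."""
        key = (chain, int(resnum), normalize_atom_name(name))
        idx = self._index.get(key)
        if idx is None:
            return Unresolvable(f"atom {key} not in structure")
        return idx

    def atom_table_signature(self):
        return tuple((a.chain, a.resnum, a.resname, a.name) for a in self.atoms)


class Ensemble:
    """Ordered frames sharing one atom table, with replicate metadata."""

    def __init__(self, structure: Structure, replicate: int = 1,
                 label: str = "", source: str = "", stride: float = 1.0):
        if replicate < 1:
            raise ValueError("replicate index must be >= 1")
        self.structure = structure
        self.replicate = int(replicate)
        self.label = label
        self.source = source
        self.stride = float(stride)

    @property
    def n_frames(self) -> int:
        return self.structure.n_models

    def frame(self, i: int) -> np.ndarray:
        return self.structure.coords[i]


# ---------------------------------------------------------------------------
# PDB I/O (gemmi-backed)
# ---------------------------------------------------------------------------

def _structure_from_gemmi(st: gemmi.Structure) -> Structure:
    models = list(st)
    if not models:
        raise FormatError("no models in file")
    atoms: list[Atom] = []
    per_model: list[list] = []
    signature = None
    for mi, model in enumerate(models):
        this_atoms: list[Atom] = []
        this_xyz: list[tuple] = []
        for chain in model:
            for res in chain:
                for at in res:
                    this_atoms.append(
                        Atom(
                            chain=chain.name,
                            resnum=res.seqid.num,
                            resname=res.name.strip(),
                            name=normalize_atom_name(at.name),
                            element=at.element.name,
                        )
                    )
                    this_xyz.append((at.pos.x, at.pos.y, at.pos.z))
        sig = tuple((a.chain, a.resnum, a.name) for a in this_atoms)
        if signature is None:
            signature = sig
            atoms = this_atoms
        elif sig != signature:
            raise ConsistencyError("models have differing atom tables")
        per_model.append(this_xyz)
    if not atoms:
        raise FormatError("zero atoms in file")
    return Structure(atoms, np.asarray(per_model, dtype=float))


def read_structure(path) -> Structure:
    """Read a single- or multi-model PDB file into a Structure.

    Atom names are normalized (star/prime dialects unified) at read time.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:
        raise IOError(f"cannot parse {path}: {exc}") from exc
    return _structure_from_gemmi(st)


def read_structure_text(text: str) -> Structure:
    """Read a PDB document from a string (convenience for fixtures)."""
    st = gemmi.read_pdb_string(text)
    return _structure_from_gemmi(st)


def read_ensemble(paths, annotation=None, replicate: int = 1,
                  label: str = "") -> Ensemble:
    """Concatenate one or more (multi-model) PDB files into an Ensemble.

    Frames are ordered path-then-model.  All files must share one atom table
    after name normalization.
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    paths = [Path(p) for p in paths]
    if not paths:
        raise ValueError("no input paths")
    parts = [read_structure(p) for p in paths]
    sig0 = parts[0].atom_table_signature()
    for p, part in zip(paths[1:], parts[1:]):
        if part.atom_table_signature() != sig0:
            raise ConsistencyError(f"atom table of {p} differs from {paths[0]}")
    coords = np.concatenate([p.coords for p in parts], axis=0)
    st = Structure(parts[0].atoms, coords)
    ens = Ensemble(st, replicate=replicate, label=label,
                   source=";".join(str(p) for p in paths))
    if annotation is not None:
        annotation.validate_against(st)
    return ens


def write_ensemble(ensemble_or_structure, path) -> None:
    """Write frames as a multi-model PDB via gemmi."""
    st = getattr(ensemble_or_structure, "structure", ensemble_or_structure)
    # group atom indices by chain, then residue, preserving file order
    chain_order: list[str] = []
    residues: dict[str, list[tuple[int, str, list[int]]]] = {}
    for i, a in enumerate(st.atoms):
        if a.chain not in residues:
            residues[a.chain] = []
            chain_order.append(a.chain)
        res_list = residues[a.chain]
        if not res_list or res_list[-1][0] != a.resnum:
            res_list.append((a.resnum, a.resname, []))
        res_list[-1][2].append(i)
    gst = gemmi.Structure()
    gst.name = "kturn"
    for mi in range(st.n_models):
        model = gemmi.Model(mi + 1)
        xyz = st.coords[mi]
        for chain_name in chain_order:
            ch = gemmi.Chain(chain_name)
            for resnum, resname, idxs in residues[chain_name]:
                res = gemmi.Residue()
                res.name = resname
                res.seqid = gemmi.SeqId(resnum, " ")
                for i in idxs:
                    a = st.atoms[i]
                    at = gemmi.Atom()
                    at.name = a.name
                    at.element = gemmi.Element(a.element or a.name[0])
                    at.pos = gemmi.Position(*xyz[i])
                    res.add_atom(at)
                ch.add_residue(res)
            model.add_chain(ch)
        gst.add_model(model)
    gst.setup_entities()
    Path(path).write_text(gst.make_pdb_string())


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

#: the core role labels of the kink-turn nomenclature (Kt-7 layout):
#: b = bulged strand, n = non-bulged strand; negative numbers are the C-stem,
#: positive the NC-stem, L the bulge loop.
CORE_ROLES = (
    "C_-1b", "G_-1n", "G_1b", "A_1n", "A_2b",
    "G_2n", "A_3b", "G_3n", "G_L1", "A_L2", "A_L3",
)


def _role_tags(role: str) -> tuple[str, str]:
    """(strand, region) inferred from a role label like 'A_2b' or 'G_L1'."""
    suffix = role.split("_", 1)[1] if "_" in role else role
    if suffix.startswith("L"):
        return "b", "bulge"
    strand = suffix[-1] if suffix[-1] in ("b", "n") else "?"
    region = "C-stem" if suffix.startswith("-") else "NC-stem"
    return strand, region


@dataclass
class KinkTurnAnnotation:
    """Role label -> (chain, residue number), with strand/region tags."""

    roles: dict[str, tuple[str, int]]
    strand: dict[str, str] = field(default_factory=dict)
    region: dict[str, str] = field(default_factory=dict)
    missing: tuple[str, ...] = ()
    suite_overrides: dict = field(default_factory=dict)

    def __post_init__(self):
        for role in self.roles:
            if role not in self.strand or role not in self.region:
                s, r = _role_tags(role)
                self.strand.setdefault(role, s)
                self.region.setdefault(role, r)

    def __contains__(self, role: str) -> bool:
        return role in self.roles

    def __len__(self) -> int:
        return len(self.roles)

    def residue(self, role: str) -> tuple[str, int]:
        if role not in self.roles:
            raise KeyError(f"role {role!r} not in annotation")
        return self.roles[role]

    def validate_against(self, structure: Structure) -> list[str]:
        """Roles whose residue has no atoms in the structure (warned)."""
        present = {(a.chain, a.resnum) for a in structure.atoms}
        absent = [r for r, key in self.roles.items() if key not in present]
        if absent:
            warnings.warn(
                f"annotation roles with no atoms in structure: {absent}",
                stacklevel=2,
            )
        return absent


class _StrictLoader(yaml.SafeLoader):
    """SafeLoader that rejects duplicate mapping keys (YAML merges them)."""


def _strict_map(loader, node, deep=False):
    mapping = {}
    for key_node, value_node in node.value:
        key = loader.construct_object(key_node, deep=deep)
        if key in mapping:
            raise AnnotationError(f"duplicate role {key!r}")
        mapping[key] = loader.construct_object(value_node, deep=deep)
    return mapping


_StrictLoader.add_constructor(
    yaml.resolver.BaseResolver.DEFAULT_MAPPING_TAG, _strict_map)


def load_annotation(source) -> KinkTurnAnnotation:
    """Load a role->residue mapping from YAML/JSON text, a dict, or a path.

    Expected shape::

        roles:
          G_L1: {chain: A, resnum: 7}
          A_1n: [A, 12]          # list form accepted
    """
    if isinstance(source, dict):
        data = source
    else:
        text = Path(source).read_text() if _looks_like_path(source) else source
        data = yaml.load(text, Loader=_StrictLoader)
    if not isinstance(data, dict):
        raise AnnotationError("annotation config must be a mapping")
    raw = data.get("roles", data)
    roles: dict[str, tuple[str, int]] = {}
    for role, value in raw.items():
        role = str(role)
        if role in roles:
            raise AnnotationError(f"duplicate role {role!r}")
        if isinstance(value, dict):
            chain, resnum = value["chain"], value["resnum"]
        else:
            chain, resnum = value[0], value[1]
        roles[role] = (str(chain), int(resnum))
    missing = tuple(r for r in CORE_ROLES if r not in roles)
    return KinkTurnAnnotation(
        roles=roles,
        missing=missing,
        suite_overrides=data.get("suites", {}) if isinstance(data, dict) else {},
    )


def _looks_like_path(source) -> bool:
    if isinstance(source, Path):
        return True
    if isinstance(source, str) and "\n" not in source and ":" not in source:
        return Path(source).exists()
    return False


def resolve_atom(structure: Structure, annotation: KinkTurnAnnotation,
                 role: str, atom: str):
    """Index of the named atom of the role's residue, or UNRESOLVABLE.

    Raises KeyError (lookup error) if the role itself is absent from the
    annotation; a missing *atom* yields the sentinel, never a default.
    """
    chain, resnum = annotation.residue(role)  # KeyError if role unknown
    return structure.atom_index(chain, resnum, atom)


# ---------------------------------------------------------------------------
# simulation manifest
# ---------------------------------------------------------------------------

MANIFEST_COLUMNS = ("ff", "solvent", "ions", "n_sims", "length_us")


@dataclass
class SimulationManifest:
    rows: pd.DataFrame

    def __post_init__(self):
        df = self.rows
        missing = set(MANIFEST_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"manifest missing columns: {sorted(missing)}")
        if len(df):
            if (df["n_sims"] < 1).any():
                raise ValueError("number of simulations must be >= 1")
            if (df["length_us"] <= 0).any():
                raise ValueError("simulation length must be > 0")


def load_manifest(source) -> SimulationManifest:
    """Parse a CSV manifest with header ff,solvent,ions,n_sims,length_us."""
    if isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        buf = Path(source) if _looks_like_path(source) else _io.StringIO(source)
        try:
            df = pd.read_csv(buf, comment="#")
        except pd.errors.EmptyDataError:
            df = pd.DataFrame(columns=list(MANIFEST_COLUMNS))
    for col in MANIFEST_COLUMNS:
        if col not in df.columns:
            df[col] = pd.Series(dtype=float if col in ("n_sims", "length_us")
                                else object)
    try:
        df["n_sims"] = df["n_sims"].astype(int)
        df["length_us"] = df["length_us"].astype(float)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"manifest parse error: {exc}") from exc
    return SimulationManifest(df[list(MANIFEST_COLUMNS)])


def summarize_manifest(manifest: SimulationManifest) -> tuple[int, float]:
    """(total simulations, cumulative simulated time in microseconds)."""
    df = manifest.rows
    if not len(df):
        return 0, 0.0
    total = int(df["n_sims"].sum())
    cumulative = float((df["n_sims"] * df["length_us"]).sum())
    return total, cumulative


def packaged_manifest_path() -> Path:
    """Path of the packaged Kt-7 simulation manifest."""
    return Path(__file__).parent / "data" / "manifest_kt7.csv"
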