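"""Shared fixtures: hand-built structures, template frames, tiny PDB texts."""

from __future__ import annotations

import numpy as np
import pytest

from kturn.structure_io import Atom, KinkTurnAnnotation, Structure
from kturn.synthetic import TEMPLATE_RESIDUES, build_template


def make_structure(role_atoms: dict[str, dict[str, tuple]],
                   extra_atoms: list[Atom] | None = None,
                   extra_xyz: list[tuple] | None = None):
    """Build a single-model Structure from role -> {atom name: xyz}.

    Roles use the synthetic template's residue numbering, so the returned
    annotation works with every classifier.
    """
    atoms, xyz = [], []
    for role, named in role_atoms.items():
        chain, resnum, resname = TEMPLATE_RESIDUES[role]
        for name, pos in named.items():
            elem = "P" if name == "P" else name[0]
            atoms.append(Atom(chain, resnum, resname, name, elem))
            xyz.append(pos)
    if extra_atoms:
        atoms.extend(extra_atoms)
        xyz.extend(extra_xyz)
    ann = KinkTurnAnnotation(
        roles={r: (c, n) for r, (c, n, _) in TEMPLATE_RESIDUES.items()})
    return Structure(atoms, np.asarray(xyz, float)[None, :, :]), ann


@pytest.fixture(scope="session")
def default_template():
    """Crystal-like template frame: every feature in its native state."""
    return build_template()


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


MINIMAL_PDB = """\
ATOM      1  P     G A   7      11.000  10.000  10.000  1.00  0.00           P
ATOM      2  O2*   G A   7      12.500  10.000  10.000  1.00  0.00           O
ATOM      3  C1'   G A   7      13.000  11.200  10.000  1.00  0.00           C
END
"""

THREE_MODEL_PDB = "".join(
    f"MODEL     {i + 1}\n"
    "ATOM      1  C1'   A A   1      "
    f"{10.0 + i:8.3f}{10.000:8.3f}{10.000:8.3f}  1.00  0.00           C\n"
    "ATOM      2  N9    A A   1      "
    f"{12.0 + i:8.3f}{10.000:8.3f}{10.000:8.3f}  1.00  0.00           N\n"
    "ENDMDL\n"
    for i in range(3)
) + "END\n"
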