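"""Shared fixtures: all coordinate data is generated programmatically."""

from pathlib import Path

import numpy as np
import pytest

from quatstab import synthetic_data as syn
from quatstab.structure_io import StructureModel

# hand-written minimal PDB exercising SEQRES, REMARK 350, alt-locs, waters and ligands
MINI_PDB = """\
HEADER    TRANSFERASE                             01-JAN-00   XXXX
REMARK 350 BIOMOLECULE: 1
REMARK 350 APPLY THE FOLLOWING TO CHAINS: A
REMARK 350   BIOMT1   1  1.000000  0.000000  0.000000        0.00000
REMARK 350   BIOMT2   1  0.000000  1.000000  0.000000        0.00000
REMARK 350   BIOMT3   1  0.000000  0.000000  1.000000        0.00000
REMARK 350   BIOMT1   2 -1.000000  0.000000  0.000000       10.00000
REMARK 350   BIOMT2   2  0.000000 -1.000000  0.000000        0.00000
REMARK 350   BIOMT3   2  0.000000  0.000000  1.000000        0.00000
SEQRES   1 A    4  ALA GLY SER CYS
CRYST1   50.000   50.000   50.000  90.00  90.00  90.00 P 1           1
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00 10.00           N
ATOM      2  CA AALA A   1       1.458   0.000   0.000  0.60 10.00           C
ATOM      3  CA BALA A   1       1.600   0.100   0.000  0.40 10.00           C
ATOM      4  C   ALA A   1       2.009   1.420   0.000  1.00 10.00           C
ATOM      5  O   ALA A   1       1.251   2.390   0.000  1.00 10.00           O
ATOM      6  N   GLY A   2       3.332   1.536   0.000  1.00 10.00           N
ATOM      7  CA  GLY A   2       3.988   2.828   0.000  1.00 10.00           C
HETATM    8  O   HOH A 101       8.000   8.000   8.000  1.00 20.00           O
HETATM    9  S   SO4 A 102      12.000  12.000  12.000  1.00 20.00           S
END
"""

TWO_ATOM_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00 10.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00 10.00           C
END
"""


@pytest.fixture
def mini_pdb(tmp_path) -> Path:
    p = tmp_path / "mini.pdb"
    p.write_text(MINI_PDB)
    return p


@pytest.fixture
def two_atom_pdb(tmp_path) -> Path:
    p = tmp_path / "two.pdb"
    p.write_text(TWO_ATOM_PDB)
    return p


@pytest.fixture(scope="session")
def helix15():
    return syn.make_helix_chain(15)


@pytest.fixture(scope="session")
def toy_tetramer():
    return syn.make_toy_tetramer(seed=0)


@pytest.fixture(scope="session")
def hollow_shell():
    return syn.make_sphere_body("hollow_shell", inner_radius=6.0, thickness=3.0, seed=1)


@pytest.fixture(scope="session")
def solid_cluster():
    return syn.make_sphere_body("solid_cluster", inner_radius=8.0, seed=1)


@pytest.fixture(scope="session")
def patchy_apolar():
    return syn.make_patchy_dimer(interface_apolar=True, seed=3)


@pytest.fixture(scope="session")
def patchy_null():
    return syn.make_patchy_dimer(interface_apolar=False, seed=3)


def all_coords(model_or_chain) -> np.ndarray:
    chains = model_or_chain.chains if isinstance(model_or_chain, StructureModel) else [model_or_chain]
    return np.array([a.coords for c in chains for r in c.residues for a in r.atoms])
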