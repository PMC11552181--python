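import numpy as np
import pytest

from pocketeval import FixtureSpec, make_chain_with_sites, make_prediction_set

TINY_PDB = """\
ATOM      1  N   GLY A  10       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  GLY A  10       1.450   0.000   0.000  1.00  0.00           C
ATOM      3  C   GLY A  10       2.000   1.400   0.000  1.00  0.00           C
END
"""

LIGAND_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.450   0.000   0.000  1.00  0.00           C
HETATM    3  C1  LIG A 101       5.000   0.000   0.000  1.00  0.00           C
HETATM    4  O1  LIG A 101       6.200   0.000   0.000  1.00  0.00           O
HETATM    5  O   HOH A 201       9.000   0.000   0.000  1.00  0.00           O
END
"""

SIFTS_MMCIF = """\
data_demo
loop_
_atom_site.group_PDB
_atom_site.id
_atom_site.type_symbol
_atom_site.label_atom_id
_atom_site.label_alt_id
_atom_site.label_comp_id
_atom_site.label_asym_id
_atom_site.label_entity_id
_atom_site.label_seq_id
_atom_site.pdbx_PDB_ins_code
_atom_site.Cartn_x
_atom_site.Cartn_y
_atom_site.Cartn_z
_atom_site.occupancy
_atom_site.B_iso_or_equiv
_atom_site.auth_seq_id
_atom_site.auth_asym_id
_atom_site.pdbx_PDB_model_num
_atom_site.pdbx_sifts_xref_db_num
ATOM 1 N N . ALA A 1 1 ? 0.000 0.000 0.000 1.00 0.00 10 A 1 101
ATOM 2 C CA . ALA A 1 1 ? 1.450 0.000 0.000 1.00 0.00 10 A 1 101
ATOM 3 N N . GLY A 1 2 ? 3.000 0.000 0.000 1.00 0.00 11 A 1 102
ATOM 4 C CA . GLY A 1 2 ? 4.450 0.000 0.000 1.00 0.00 11 A 1 102
"""


@pytest.fixture
def tiny_pdb(tmp_path):
    path = tmp_path / "tiny.pdb"
    path.write_text(TINY_PDB)
    return path


@pytest.fixture
def ligand_pdb(tmp_path):
    path = tmp_path / "ligand.pdb"
    path.write_text(LIGAND_PDB)
    return path


@pytest.fixture
def sifts_mmcif(tmp_path):
    path = tmp_path / "demo.cif"
    path.write_text(SIFTS_MMCIF)
    return path


@pytest.fixture(scope="session")
def helix_fixture():
    """A 100-residue helix with 3 planted 8-residue sites (seed 7)."""
    spec = FixtureSpec(seed=7)
    chain, sites, ligands = make_chain_with_sites(spec)
    return spec, chain, sites, ligands


@pytest.fixture(scope="session")
def helix_predictions(helix_fixture):
    spec, chain, sites, _ = helix_fixture
    return make_prediction_set(sites, chain, spec)


def random_coords(rng, n, scale=10.0):
    return rng.normal(size=(n, 3)) * scale
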