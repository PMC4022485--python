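import numpy as np
import pytest

from allomap.structure import Residue, StructureModel

#: Hand-written three-residue PDB fixture (ids 1-3, chain A, full backbone
#: on residue 1 so heavy-atom distances are exercised).
THREE_RESIDUE_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00 10.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00 10.00           C
ATOM      3  C   ALA A   1       2.009   1.420   0.000  1.00 10.00           C
ATOM      4  O   ALA A   1       1.251   2.390   0.000  1.00 10.00           O
ATOM      5  CA  GLY A   2       4.500   2.000   0.500  1.00 12.00           C
ATOM      6  CA  SER A   3       7.800   3.500   1.200  1.00 14.00           C
END
"""

#: Same fixture with the middle residue lacking a Cα atom.
MISSING_CA_PDB = """\
ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00 10.00           C
ATOM      2  N   GLY A   2       4.500   2.000   0.500  1.00 12.00           N
ATOM      3  CA  SER A   3       7.800   3.500   1.200  1.00 14.00           C
END
"""

#: Alternate-location fixture: conformer B has the higher occupancy.
ALTLOC_PDB = """\
ATOM      1  CA AALA A   1       0.000   0.000   0.000  0.40 10.00           C
ATOM      2  CA BALA A   1       9.000   0.000   0.000  0.60 10.00           C
ATOM      3  CA  GLY A   2       4.500   2.000   0.500  1.00 12.00           C
ATOM      4  CA  SER A   3       7.800   3.500   1.200  1.00 14.00           C
END
"""


def toy_model(coords, ids=None, chain="A", aa="A"):
    """StructureModel from bare Cα coordinates."""
    coords = np.asarray(coords, dtype=float)
    ids = ids or list(range(1, len(coords) + 1))
    return StructureModel(
        [Residue(i, chain, aa, tuple(c)) for i, c in zip(ids, coords)]
    )


@pytest.fixture
def path3_model():
    """Three collinear beads 3.8 Å apart (path graph at the GNM cutoff)."""
    return toy_model([(0, 0, 0), (3.8, 0, 0), (7.6, 0, 0)])


@pytest.fixture
def triangle_model():
    """Equilateral triangle, all pairs within the GNM cutoff."""
    return toy_model([(0, 0, 0), (3.8, 0, 0), (1.9, 3.29, 0)])


@pytest.fixture
def cloud_model():
    """Well-connected random 10-node cloud for ANM tests."""
    rng = np.random.default_rng(7)
    return toy_model(rng.uniform(0, 10, (10, 3)))


@pytest.fixture
def three_residue_pdb(tmp_path):
    p = tmp_path / "three.pdb"
    p.write_text(THREE_RESIDUE_PDB)
    return str(p)


@pytest.fixture
def missing_ca_pdb(tmp_path):
    p = tmp_path / "missing_ca.pdb"
    p.write_text(MISSING_CA_PDB)
    return str(p)


@pytest.fixture
def altloc_pdb(tmp_path):
    p = tmp_path / "altloc.pdb"
    p.write_text(ALTLOC_PDB)
    return str(p)
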