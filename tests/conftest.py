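import numpy as np
import pytest

from ankgroove.structure_io import Atom, Residue, Structure
from ankgroove.synthetic_data import GeometryFixtureSpec, make_geometry_fixture

MINIMAL_PDB = """\
ATOM      1  N   ALA A   7      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  ALA A   7      11.639   6.071  -5.147  1.00  0.00           C
END
"""


@pytest.fixture
def minimal_pdb(tmp_path):
    path = tmp_path / "minimal.pdb"
    path.write_text(MINIMAL_PDB)
    return path


@pytest.fixture
def hbond_structure():
    return make_geometry_fixture(GeometryFixtureSpec("hbond", 2.9, 165.0))


@pytest.fixture
def hydrophobic_structure():
    return make_geometry_fixture(GeometryFixtureSpec("hydrophobic", 4.0))


@pytest.fixture
def far_apart_structure():
    """Two Leu residues with every atom pair > 100 A apart."""
    spec = GeometryFixtureSpec("none", 110.0)
    return make_geometry_fixture(spec)


def single_atom_structure(radius=1.9, chain="A", name="X1"):
    atom = Atom(name=name, element="C", coord=np.zeros(3), vdw_radius=radius)
    res = Residue(chain_id=chain, number=1, aa="X", resname="UNK", atoms=[atom])
    return Structure(id="single", chains={chain: [res]})
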