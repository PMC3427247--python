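import numpy as np
import pytest

from funsav.io_formats import Atom, Chain, Residue, Structure
from funsav.synthetic import SyntheticSpec, make_structure


@pytest.fixture(scope="session")
def helix20():
    """20-residue ideal α-helix with full backbone + Cβ."""
    return make_structure(SyntheticSpec(seed=1, n_residues=20, geometry="ideal-helix"))


@pytest.fixture(scope="session")
def extended20():
    return make_structure(SyntheticSpec(seed=1, n_residues=20, geometry="extended"))


def point_structure(coords, resname="GLY", atom_name="CA", element="C"):
    """Structure of single-atom residues at the given coordinates."""
    residues = [
        Residue(seqnum=i + 1, icode=" ", name=resname,
                atoms=[Atom(atom_name, element, np.asarray(c, float))])
        for i, c in enumerate(coords)
    ]
    return Structure(id="points", chains=[Chain(id="A", residues=residues)])


@pytest.fixture
def path3():
    """Three single-atom residues in a line 5 Å apart (path contact graph)."""
    return point_structure([(0, 0, 0), (5, 0, 0), (10, 0, 0)])
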