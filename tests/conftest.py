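import numpy as np
import pytest

from pulsefield.core import Atom, Frame, Topology


@pytest.fixture
def water_ion_protein_topology():
    """Tiny mixed-species topology: 4 protein, 3 water-O, 9 Na ions."""
    atoms = []
    i = 0
    for name in ("N", "CA", "C", "O"):
        atoms.append(Atom(index=i, name=name, residue_name="GLY",
                          residue_id=1, species="protein", mass=12.0))
        i += 1
    for w in range(3):
        atoms.append(Atom(index=i, name="OW", residue_name="SOL",
                          residue_id=2 + w, species="water", mass=16.0))
        i += 1
    for n in range(9):
        atoms.append(Atom(index=i, name="NA", residue_name="NA",
                          residue_id=5 + n, species="ion", charge=1.0,
                          mass=23.0))
        i += 1
    return Topology(atoms)


@pytest.fixture
def tiny_gro(tmp_path):
    """A 3-atom GRO file with a box, written by hand."""
    text = (
        "test system t= 0.5\n"
        "    3\n"
        "    1GLY      N    1   1.000   2.000   3.000\n"
        "    1GLY     CA    2   1.100   2.100   3.100\n"
        "    2SOL     OW    3   4.000   5.000   6.000\n"
        "  10.00000  11.00000   9.00000\n"
    )
    path = tmp_path / "tiny.gro"
    path.write_text(text)
    return path


@pytest.fixture
def tiny_pdb(tmp_path):
    """A 2-atom PDB file (coordinates in Angstrom)."""
    text = (
        "ATOM      1  N   GLY A   1      10.000  20.000  30.000  1.00  0.00"
        "           N\n"
        "ATOM      2  CA  GLY A   1      11.000  21.000  31.000  1.00  0.00"
        "           C\n"
        "END\n"
    )
    path = tmp_path / "tiny.pdb"
    path.write_text(text)
    return path


@pytest.fixture
def dipole_pair():
    """+1/-1 e pair 1 nm apart along z: dipole (0, 0, 1) e·nm."""
    atoms = [
        Atom(index=0, name="P", residue_name="DIP", residue_id=1,
             charge=1.0, mass=1.0),
        Atom(index=1, name="M", residue_name="DIP", residue_id=1,
             charge=-1.0, mass=1.0),
    ]
    topo = Topology(atoms)
    frame = Frame(time=0.0,
                  positions=np.array([[0.0, 0.0, 0.5], [0.0, 0.0, -0.5]]))
    return topo, frame
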