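import numpy as np
import pytest

from surfbind import AtomRecord, Frame, MolecularSystem


def make_atom(serial, name="C1", element="C", resname="ALA", resindex=1,
              chain="A", charge=0.0, c6=0.0, c12=0.0, group="other"):
    return AtomRecord(
        serial=serial, name=name, element=element, residue_name=resname,
        residue_index=resindex, chain=chain, charge=charge, c6=c6, c12=c12,
        group=group,
    )


@pytest.fixture
def donor_acceptor_system():
    """Water-like donor (O, H) plus two acceptor oxygens, coordinates set
    per test via a Frame."""
    atoms = [
        make_atom(1, "OD", "O", "LIG", 1, "B", group="head"),
        make_atom(2, "HD", "H", "LIG", 1, "B", group="head"),
        make_atom(3, "OA1", "O", "SER", 10, "A", group="protein"),
        make_atom(4, "OA2", "O", "THR", 11, "A", group="protein"),
    ]
    return MolecularSystem(atoms=atoms, donors=[(0, 1)], acceptors=[2, 3])


def frame(coords, box=None, time=0.0):
    return Frame(time=time, coordinates=np.asarray(coords, dtype=float),
                 box=box)
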