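import io

import pytest

from mfccbind.energies import ClassicalBackend
from mfccbind.structures import read_complex, write_complex_pdb
from mfccbind.toys import ToySpec, assign_toy_parameters, build_toy_complex

FIVE_SEQ = ("GLY", "ALA", "SER", "ASP", "LYS")


@pytest.fixture(scope="session")
def toy_spec():
    return ToySpec(sequence=FIVE_SEQ, probe="diatomic_dipole", anchor_index=3, offset=3.5)


@pytest.fixture(scope="session")
def toy_complex(toy_spec):
    return build_toy_complex(toy_spec)


@pytest.fixture(scope="session")
def toy_params(toy_complex, toy_spec):
    return assign_toy_parameters(toy_complex, toy_spec)


@pytest.fixture()
def toy_backend(toy_params):
    return ClassicalBackend(toy_params)


@pytest.fixture()
def toy_pdb_text(toy_complex):
    buf = io.StringIO()
    write_complex_pdb(toy_complex, buf)
    return buf.getvalue()


def reread(pdb_text: str, ligand_resname: str = "PRB", **kw):
    return read_complex(io.StringIO(pdb_text), ligand_resname, **kw)
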