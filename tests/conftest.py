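import numpy as np
import pytest

from conformetrics import toy_structure


@pytest.fixture(scope="session")
def helix30():
    return toy_structure(30, "helix")


@pytest.fixture(scope="session")
def two_domain100():
    return toy_structure(100, "two-domain", seed=0)


@pytest.fixture(scope="session")
def two_domain60():
    return toy_structure(60, "two-domain", seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def tiny_pdb(tmp_path):
    """Hand-written 3-residue PDB with an altloc pair on residue 1."""
    text = (
        "ATOM      1  CA AALA A   1      11.000  12.000  13.000  0.40 10.00"
        "           C\n"
        "ATOM      2  CA BALA A   1      21.000  22.000  23.000  0.60 10.00"
        "           C\n"
        "ATOM      3  CA  GLY A   2       1.000   2.000   3.000  1.00 10.00"
        "           C\n"
        "ATOM      4  CA  SER A   3       4.000   5.000   6.000  1.00 10.00"
        "           C\n"
        "END\n"
    )
    path = tmp_path / "tiny.pdb"
    path.write_text(text)
    return path
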