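import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("default", derandomize=True, max_examples=25)
settings.load_profile("default")


@pytest.fixture(scope="session")
def toy():
    """Standard toy receptor: 2 helices, 13-residue loop, one disulfide."""
    from ecloop.fixtures import make_toy_receptor
    return make_toy_receptor(n_helices=2, helix_len=12, loop_len=13, seed=0)


@pytest.fixture(scope="session")
def toy_cg(toy):
    from ecloop.cg_model import allatom_to_cg
    return allatom_to_cg(toy.structure, [toy.loop])


@pytest.fixture(scope="session")
def ideal_helix_trace():
    from ecloop.fixtures import ideal_helix
    return ideal_helix(12, np.zeros(2), 0.0)


@pytest.fixture()
def tiny_pdb(tmp_path):
    """Hand-written 3-residue PDB file."""
    text = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.009   1.420   0.000  1.00  0.00           C
ATOM      4  CB  ALA A   1       1.988  -0.773  -1.199  1.00  0.00           C
ATOM      5  N   GLY A   2       3.332   1.536   0.000  1.00  0.00           N
ATOM      6  CA  GLY A   2       3.988   2.831   0.122  1.00  0.00           C
ATOM      7  C   GLY A   2       5.480   2.705   0.081  1.00  0.00           C
ATOM      8  N   SER A   3       6.101   3.869   0.203  1.00  0.00           N
ATOM      9  CA  SER A   3       7.553   3.946   0.187  1.00  0.00           C
ATOM     10  C   SER A   3       8.059   5.371   0.311  1.00  0.00           C
ATOM     11  CB  SER A   3       8.133   3.342  -1.090  1.00  0.00           C
ATOM     12  OG  SER A   3       7.766   1.979  -1.211  1.00  0.00           O
END
"""
    path = tmp_path / "tiny.pdb"
    path.write_text(text)
    return path
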