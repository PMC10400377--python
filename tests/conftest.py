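import numpy as np
import pytest

from pualign.synthetic import (
    make_circular_permutation,
    make_hinge_bend,
    make_two_domain,
)

MINI_PDB = """\
ATOM      1  N   ALA A   1      -1.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      3  CA  GLY A   2       3.800   0.000   0.000  1.00  0.00           C
ATOM      4  CA  SER A   3       7.600   0.000   0.000  1.00  0.00           C
END
"""

TWO_CHAIN_PDB = """\
ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      2  CA  ALA A   2       3.800   0.000   0.000  1.00  0.00           C
ATOM      3  CA  ALA A   3       7.600   0.000   0.000  1.00  0.00           C
ATOM      4  CA  GLY B   1       0.000   5.000   0.000  1.00  0.00           C
ATOM      5  CA  GLY B   2       3.800   5.000   0.000  1.00  0.00           C
ATOM      6  CA  GLY B   3       7.600   5.000   0.000  1.00  0.00           C
ATOM      7  CA  GLY B   4      11.400   5.000   0.000  1.00  0.00           C
END
"""


@pytest.fixture
def mini_pdb(tmp_path):
    p = tmp_path / "mini.pdb"
    p.write_text(MINI_PDB)
    return p


@pytest.fixture
def two_chain_pdb(tmp_path):
    p = tmp_path / "two_chain.pdb"
    p.write_text(TWO_CHAIN_PDB)
    return p


@pytest.fixture
def two_domain():
    """80-residue chain of two compact 40-residue domains."""
    return make_two_domain(40, 40, seed=2)


@pytest.fixture
def cp_pair(two_domain):
    """Circular permutation of the two-domain chain, with ground truth."""
    permuted, gt = make_circular_permutation(two_domain, cut=40, seed=7,
                                             noise_sigma=0.3)
    return two_domain, permuted, gt


@pytest.fixture
def hinge_pair(two_domain):
    bent, gt = make_hinge_bend(two_domain, hinge=40, angle=45.0, seed=3,
                               noise_sigma=0.3)
    return two_domain, bent, gt


def random_rigid(rng):
    """Uniform random rotation + bounded translation."""
    M = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(M)
    Q *= np.sign(np.diag(R))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q, rng.uniform(-20, 20, size=3)
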