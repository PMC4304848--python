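import numpy as np
import pytest

from quadpot.potential import (QuadrupletPotential, enumerate_quadruplets,
                               train_potential)
from quadpot.synthetic_data import (SyntheticSpec, corpus_tessellations,
                                    generate_corpus, generate_structure)
from quadpot.tessellation import tessellate_structure

TOY_PDB = """\
HEADER    TOY
HELIX    1   1 ALA A    1  GLY A    2  1
SHEET    1   A 2 CYS A   3  MET A   4  0
ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      2  CA  GLY A   2       3.800   0.000   0.000  1.00  0.00           C
ATOM      3  CA  CYS A   3       1.900   3.291   0.000  1.00  0.00           C
ATOM      4  CA  MET A   4       1.900   1.100   3.100  1.00  0.00           C
END
"""


@pytest.fixture(scope="session")
def toy_pdb_text():
    return TOY_PDB


@pytest.fixture(scope="session")
def corpus():
    return generate_corpus(8, (60, 100), seed=1)


@pytest.fixture(scope="session")
def trained_potential(corpus):
    return train_potential(corpus_tessellations(corpus))


@pytest.fixture(scope="session")
def structure():
    return generate_structure(SyntheticSpec(n_residues=120, seed=7))


@pytest.fixture(scope="session")
def tess(structure):
    return tessellate_structure(structure)


@pytest.fixture(scope="session")
def random_score_potential():
    """A potential with distinct random scores for every quadruplet.

    Useful where analytically distinct scores are needed (e.g. checking
    that EP support covers the whole structural neighborhood).
    """
    rng = np.random.default_rng(42)
    keys = enumerate_quadruplets()
    s = {k: float(v) for k, v in zip(keys, rng.normal(0, 1, len(keys)))}
    return QuadrupletPotential(
        counts={k: 0 for k in keys}, f={k: 1 / len(keys) for k in keys},
        p={k: 1 / len(keys) for k in keys}, s=s,
        composition={aa: 0.05 for aa in "ACDEFGHIKLMNPQRSTVWY"},
        metadata={"synthetic": True})
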