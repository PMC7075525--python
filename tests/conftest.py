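"""Shared fixtures: small structures and the standard synthetic corpus."""

import numpy as np
import pytest

from protqa.pipeline import make_bundles, train_checkpoints
from protqa.synth import SyntheticScenario, make_native


GAG_PDB = """\
ATOM      1  N   GLY A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  GLY A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   GLY A   1       2.009   1.420   0.000  1.00  0.00           C
ATOM      4  O   GLY A   1       1.251   2.390   0.000  1.00  0.00           O
ATOM      5  N   ALA A   2       3.332   1.536   0.000  1.00  0.00           N
ATOM      6  CA  ALA A   2       4.000   2.800   0.000  1.00  0.00           C
ATOM      7  C   ALA A   2       5.500   2.700   0.000  1.00  0.00           C
ATOM      8  O   ALA A   2       6.100   1.640   0.000  1.00  0.00           O
ATOM      9  CB  ALA A   2       3.500   3.600   1.200  1.00  0.00           C
ATOM     10  N   GLY A   3       6.100   3.900   0.000  1.00  0.00           N
ATOM     11  CA  GLY A   3       7.500   4.000   0.000  1.00  0.00           C
ATOM     12  C   GLY A   3       8.100   5.400   0.000  1.00  0.00           C
ATOM     13  O   GLY A   3       7.400   6.420   0.000  1.00  0.00           O
END
"""


@pytest.fixture
def gag_pdb(tmp_path):
    path = tmp_path / "gag.pdb"
    path.write_text(GAG_PDB)
    return path


@pytest.fixture(scope="session")
def helix_native():
    return make_native(SyntheticScenario(seed=5, length=24,
                                         layout="C" + "H" * 22 + "C"))


def random_structure(rng, length=None):
    """Small random clash-free structure for oracle comparisons."""
    length = length or int(rng.integers(5, 30))
    return make_native(SyntheticScenario(seed=int(rng.integers(2 ** 31)),
                                         length=length))


@pytest.fixture(scope="session")
def standard_corpus(tmp_path_factory):
    """The standard synthetic study corpus: 30 targets x 8 models with
    coordinate noise spanning 0-3 A, seed 7; trained checkpoints and the
    assembled per-residue dataset."""
    out = tmp_path_factory.mktemp("corpus")
    bundles = make_bundles(30, seed=7, out_dir=out)
    checkpoints, dataset = train_checkpoints(bundles, seed=7,
                                             corpus_size=150)
    return bundles, checkpoints, dataset


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def checkpoint_dir(standard_corpus, tmp_path_factory):
    """Trained checkpoints of the standard corpus, saved to disk."""
    bundles, checkpoints, dataset = standard_corpus
    path = tmp_path_factory.mktemp("checkpoints")
    checkpoints.save(path)
    return path
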