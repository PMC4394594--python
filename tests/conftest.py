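import dendropy
import numpy as np
import pytest

from wingrda.io import CharacterMatrix, load_study_fixture


def tree_from_newick(newick: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=newick, schema="newick",
                             rooting="force-rooted")


def star_tree(n: int, depth: float = 1.0) -> dendropy.Tree:
    tips = ",".join(f"t{k + 1}:{depth}" for k in range(n))
    return tree_from_newick(f"({tips});")


@pytest.fixture(scope="session")
def study():
    return load_study_fixture()


@pytest.fixture(scope="session")
def study_characters(study):
    return study[0]


@pytest.fixture(scope="session")
def study_traits(study):
    return study[1]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_character_matrix(rng, n_taxa: int = 8) -> CharacterMatrix:
    scores = rng.integers(0, 3, size=(n_taxa, 6))
    scores[:, 3] = rng.integers(0, 2, size=n_taxa)  # iip1 is binary
    return CharacterMatrix([f"t{k}" for k in range(n_taxa)], scores,
                           np.zeros(n_taxa, bool))
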