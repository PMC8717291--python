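import numpy as np
import pytest

from kipuka import Phylogeny


@pytest.fixture
def three_tip_tree() -> Phylogeny:
    """((A:1,B:1):1,C:2); — ultrametric, height 2."""
    return Phylogeny.from_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


def random_tree(rng: np.random.Generator, n_tips: int, lam: float = 1.0, mu: float = 0.0) -> Phylogeny:
    from kipuka import simulate_birth_death_tree

    return simulate_birth_death_tree(n_tips, lam, mu, rng)


@pytest.fixture
def star_tree_factory():
    """Star phylogeny: k tips attached directly to the root with equal branch length."""

    def make(k: int, height: float) -> Phylogeny:
        parent = [-1] + [0] * k
        blen = [0.0] + [height] * k
        labels = [None] + [f"t{i}" for i in range(k)]
        return Phylogeny(parent, blen, labels)

    return make
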