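import numpy as np
import pytest

from poomkit.chronogram_io import PosteriorEnsemble, read_dated_trees
from poomkit.synthetic_data import TreeSimConfig, make_posterior_ensemble, simulate_yule_tree

# Hand-built ultrametric 4-leaf chronogram with known node ages (Ma):
# root 250, MRCA(A,B) 100, MRCA(C,D) 200, tips at 0.
FOUR_LEAF_NEWICK = "((A:100,B:100):150,(C:200,D:200):50);"


@pytest.fixture(scope="session")
def four_leaf_tree():
    return read_dated_trees(FOUR_LEAF_NEWICK, burn_in=0.0).trees[0]


@pytest.fixture(scope="session")
def single_tree_ensemble():
    """Ensemble of one fixed tree; every summary reduces to node-age arithmetic."""
    return read_dated_trees(FOUR_LEAF_NEWICK, burn_in=0.0)


@pytest.fixture(scope="session")
def identical_ensemble():
    """Ten identical copies of the 4-leaf chronogram, no burn-in."""
    return read_dated_trees("\n".join([FOUR_LEAF_NEWICK] * 10), burn_in=0.0)


@pytest.fixture(scope="session")
def yule_tree():
    """A moderately sized constant-rate tree used across modules."""
    cfg = TreeSimConfig.constant(rate=0.002, root_age=2000.0, seed=11)
    tree = simulate_yule_tree(cfg)
    assert tree.n_leaves >= 5
    return tree


@pytest.fixture(scope="session")
def jittered_ensemble(yule_tree):
    """Posterior-style ensemble around the fixture topology (cv 5%, n=50)."""
    return make_posterior_ensemble(yule_tree, n_trees=50, age_jitter_cv=0.05, seed=12)


@pytest.fixture()
def rng():
    return np.random.default_rng(2026)
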