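import numpy as np
import pytest

from lineaburst import simdata, treekit


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_chronogram():
    """4-tip caterpillar with node ages 10, 6, 3."""
    return treekit.read_newick("(((A:3,B:3):3,C:6):4,D:10);")


@pytest.fixture
def random_trees():
    """20 small random Yule chronograms (varied size and rate)."""
    trees = []
    for s in range(20):
        n = 5 + (s % 8)
        trees.append(simdata.sim_yule(n, 0.2 + 0.1 * (s % 4), seed=900 + s))
    return trees


@pytest.fixture
def species_gene_tree():
    """Gene tree with 10 deep species, 4 samples each, plus truth labels."""
    sp = simdata.sim_yule(10, 0.05, seed=100)
    gene, truth = simdata.sim_species_coalescent(sp, 4, 0.05, seed=200)
    return sp, gene, truth
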