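import numpy as np
import pytest

from genescape import LandscapeConfig, NodeSet, Population


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    """50 km x 50 km landscape, quick to synthesize."""
    return LandscapeConfig(n_rows=100, n_cols=100, cell_size=500.0,
                           aggregation_length=5000.0, seed=11)


def make_population(genotypes, sexes=None, nodes=None):
    """Build a Population from a nested list of per-individual genotypes
    [[(a, b) per locus] per individual]."""
    geno = np.asarray(genotypes, dtype=np.int16)
    n = geno.shape[0]
    sex = np.asarray(sexes if sexes is not None else [1, 0] * (n // 2 + 1))[:n]
    node = np.asarray(nodes if nodes is not None else np.zeros(n, dtype=int))
    return Population(ids=np.arange(n), sex=sex.astype(np.int8), node=node, genotype=geno)


@pytest.fixture
def grid_nodes():
    """Four nodes on a 10 km spacing grid."""
    return NodeSet(np.arange(4), np.array([5e3, 15e3, 5e3, 15e3]),
                   np.array([5e3, 5e3, 15e3, 15e3]))
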