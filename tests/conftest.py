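import numpy as np
import pytest

from qtltree.bmg_tree import build_tree
from qtltree.datasets import example_genotypes
from qtltree.genotype_io import BMGMatrix, GenotypeMatrix, recode_to_bmg


@pytest.fixture(scope="session")
def example_matrix() -> GenotypeMatrix:
    """The built-in 100-individual, four-site worked example."""
    return example_genotypes()


@pytest.fixture(scope="session")
def example_tree(example_matrix):
    return build_tree(recode_to_bmg(example_matrix, "GENE1"))


def random_bmg(rng: np.random.Generator, n_individuals=None, n_sites=None,
               gene: str = "G") -> BMGMatrix:
    """A random binary multilocus genotype matrix with rare-skewed bits."""
    n = n_individuals or int(rng.integers(3, 15))
    m = n_sites or int(rng.integers(1, 6))
    freqs = rng.uniform(0.05, 0.6, size=m)
    codes = (rng.random((n, m)) < freqs).astype(np.uint8)
    return BMGMatrix(gene=gene, codes=codes, site_ids=[f"s{j}" for j in range(m)])


def random_tree(rng: np.random.Generator, max_nodes: int = 25):
    """A random genotype tree with at most ``max_nodes`` nodes."""
    while True:
        tree = build_tree(random_bmg(rng))
        if tree.n_nodes <= max_nodes:
            return tree


def make_matrix(counts, gene="G1", populations=None) -> GenotypeMatrix:
    counts = np.asarray(counts, dtype=np.int8)
    n, m = counts.shape
    return GenotypeMatrix(
        counts=counts,
        site_ids=[f"{gene}_s{j}" for j in range(m)],
        site_positions=np.arange(1, m + 1),
        site_genes=np.array([gene] * m, dtype=object),
        individual_ids=[f"I{i}" for i in range(n)],
        individual_population=np.array(populations or ["all"] * n, dtype=object),
    )
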