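import numpy as np
import pytest

from pathxtalk.gene_sets import GeneSetCollection, MembershipMatrix, build_membership


def make_membership(pathways: dict, de_genes, alpha: float = 0.05) -> MembershipMatrix:
    """Build a membership matrix from explicit sets and a DE gene list.

    Synthetic ordering p-values are assigned deterministically: DE genes get
    tiny p-values, the rest large ones, so the DE-first row convention holds
    without running an actual test.
    """
    collection = GeneSetCollection(
        tuple((pid, frozenset(genes)) for pid, genes in pathways.items())
    )
    de = set(de_genes)
    pvals = {}
    for i, g in enumerate(sorted(collection.genes)):
        pvals[g] = (0.001 if g in de else 0.5) + 1e-6 * i
    return build_membership(collection, pvals, alpha=alpha)


@pytest.fixture
def toy_membership():
    return make_membership


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
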