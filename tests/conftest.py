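import numpy as np
import pytest

from ileodef.diversity import OtuTable, PhyloTree


@pytest.fixture
def toy_tree() -> PhyloTree:
    """((A:1,B:2):0.5,C:3):0 — the hand-checkable three-leaf tree."""
    return PhyloTree.from_newick("((A:1,B:2):0.5,C:3):0.0;")


@pytest.fixture
def toy_otu_ids() -> list[str]:
    return ["A", "B", "C"]


def random_table_and_tree(seed: int, n_samples: int = 6, n_otus: int = 12):
    """Random OTU table + random binary tree for oracle comparisons."""
    rng = np.random.default_rng(seed)
    otu_ids = [f"O{i}" for i in range(n_otus)]
    counts = rng.integers(0, 30, size=(n_samples, n_otus))
    counts[counts < 8] = 0  # plenty of absences
    for row in counts:  # UniFrac needs non-empty samples
        if row.sum() == 0:
            row[rng.integers(n_otus)] = 5
    table = OtuTable([f"s{i}" for i in range(n_samples)], otu_ids, counts)

    from ileodef.cohort import random_coalescent_newick

    newick = random_coalescent_newick(otu_ids, rng, 0.5)
    return table, PhyloTree.from_newick(newick), newick
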