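import numpy as np
import pytest

from mobkit.io_core import OtuTable, parse_tree_newick


@pytest.fixture
def three_tip_tree():
    """((A:1,B:1):1,C:2); — d(A,B)=2, d(A,C)=d(B,C)=4."""
    return parse_tree_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def toy_table():
    counts = np.array(
        [
            [5, 3, 0, 2],
            [0, 4, 4, 2],
            [1, 1, 1, 7],
        ]
    )
    return OtuTable(counts, ("S1", "S2", "S3"), ("A", "B", "C", "D"))


def random_table(rng, n_samples=6, n_otus=10, depth=200):
    """Random multinomial table where every sample has >= 2 present OTUs."""
    while True:
        probs = rng.dirichlet(np.ones(n_otus))
        counts = rng.multinomial(depth, probs, size=n_samples)
        if ((counts > 0).sum(axis=1) >= 2).all():
            return OtuTable(
                counts,
                tuple(f"S{i}" for i in range(n_samples)),
                tuple(f"O{j}" for j in range(n_otus)),
            )
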