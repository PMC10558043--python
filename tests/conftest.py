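import numpy as np
import pytest

from ccinet import (
    ClusterLabels,
    ExpressionMatrix,
    LigandReceptorPair,
    LRIDBTable,
    SyntheticSpec,
    simulate_counts,
)


@pytest.fixture(scope="session")
def small_counts():
    """300 cells x 120 genes, 3 planted clusters, strong markers."""
    spec = SyntheticSpec(n_cells=300, n_genes=120, n_clusters=3, de_strength=8.0,
                         markers_per_cluster=15, seed=5)
    return simulate_counts(spec)


@pytest.fixture
def tiny_matrix():
    values = np.array([
        [0.0, 2.0, 4.0],
        [1.0, 0.0, 1.0],
        [3.0, 3.0, 3.0],
        [0.0, 0.0, 0.0],
    ])
    return ExpressionMatrix(values, [f"g{i}" for i in range(4)], ["a", "b", "c"])


@pytest.fixture
def toy_pairs():
    mk = LigandReceptorPair
    return [
        mk(("TGFB1",), ("TGFBR1", "TGFBR2"), "human", sources=("dbA",)),
        mk(("NAMPT",), ("ITGA5", "ITGB1"), "human", sources=("dbB",)),
        mk(("CCL19",), ("CCR7",), "human", sources=("dbA", "dbB")),
    ]


@pytest.fixture
def toy_table(toy_pairs):
    return LRIDBTable(list(toy_pairs), "human")
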