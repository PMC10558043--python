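"""Graph construction: KNN cell graph, adjacency normalization, Louvain
cluster-number estimation, and the ligand-receptor pair correlation graph.

The cell graph links every cell to its K nearest neighbors in feature space
(Euclidean), symmetrized by union, and is consumed by the graph-convolutional
branch of the cluster model after the standard D^-1/2 (A+I) D^-1/2
renormalization.  The pair graph connects highly scoring ligand-receptor pairs
whose interaction-probability profiles across cluster pairs are strongly
correlated; it drives the GCN branch of the interaction classifier.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.spatial.distance import cdist


@dataclass
class CellGraph:
    """Binary symmetric cell-cell adjacency with zero diagonal."""

    adjacency: sp.csr_matrix
    K: int

    def __post_init__(self):
        A = sp.csr_matrix(self.adjacency)
        if A.shape[0] != A.shape[1]:
            raise ValueError("adjacency must be square")
        if (A != A.T).nnz:
            raise ValueError("adjacency must be symmetric")
        if A.diagonal().any():
            raise ValueError("adjacency must have zero diagonal")
        self.adjacency = A

    @property
    def n_cells(self) -> int:
        return self.adjacency.shape[0]

    def to_networkx(self) -> nx.Graph:
        return nx.from_scipy_sparse_array(self.adjacency)

    def write_edgelist(self, path) -> None:
        coo = sp.triu(self.adjacency).tocoo()
        pd.DataFrame({"node_u": coo.row, "node_v": coo.col, "weight": coo.data}).to_csv(
            path, sep="\t", index=False
        )


@dataclass
class LRPairGraph:
    """Top-N ligand-receptor pairs with a thresholded-correlation adjacency."""

    pair_names: list
    scores: np.ndarray          # per-node total interaction probability
    correlation: np.ndarray     # nodes x nodes Pearson matrix
    adjacency: np.ndarray       # binary symmetric
    tau: float

    @property
    def n_nodes(self) -> int:
        return len(self.pair_names)

    def write_edgelist(self, path) -> None:
        iu = np.triu_indices(self.n_nodes, k=1)
        mask = self.adjacency[iu] > 0
        pd.DataFrame({
            "node_u": [self.pair_names[i] for i in iu[0][mask]],
            "node_v": [self.pair_names[j] for j in iu[1][mask]],
            "weight": self.correlation[iu][mask],
        }).to_csv(path, sep="\t", index=False)


def build_knn_graph(features: np.ndarray, K: int = 10) -> CellGraph:
    """Euclidean K-nearest-neighbor digraph, symmetrized by union.

    Ties are broken deterministically by ascending cell index (stable sort on
    distances).  Self-edges are excluded.
    """
    features = np.asarray(features, dtype=np.float64)
    n = features.shape[0]
    if not (1 <= K < n):
        raise ValueError(f"K must satisfy 1 <= K < n_cells (got K={K}, n={n})")
    D = cdist(features, features)
    np.fill_diagonal(D, np.inf)
    order = np.argsort(D, axis=1, kind="stable")[:, :K]
    rows = np.repeat(np.arange(n), K)
    A = sp.coo_matrix((np.ones(n * K), (rows, order.ravel())), shape=(n, n)).tocsr()
    A = ((A + A.T) > 0).astype(np.float64)  # union symmetrization
    A.setdiag(0)
    A.eliminate_zeros()
    return CellGraph(A, K)


def normalize_adjacency(A) -> sp.csr_matrix:
    """Symmetric renormalization D^-1/2 (A + I) D^-1/2 with self-loops."""
    A = sp.csr_matrix(A)
    if A.shape[0] != A.shape[1]:
        raise ValueError("adjacency must be square")
    At = A + sp.eye(A.shape[0], format="csr")
    d = np.asarray(At.sum(axis=1)).ravel()
    dinv = 1.0 / np.sqrt(d)
    Dinv = sp.diags(dinv)
    return (Dinv @ At @ Dinv).tocsr()


def estimate_n_clusters(graph: CellGraph, seed: int, resolution: float = 1.0) -> int:
    """Number of Louvain communities of the cell graph at the given resolution."""
    if graph.n_cells == 0:
        raise ValueError("empty graph")
    communities = nx.algorithms.community.louvain_communities(
        graph.to_networkx(), resolution=resolution, seed=seed
    )
    return len(communities)


def build_lr_pair_graph(prob_tensor, top_n: int = 200, tau: float = 0.95,
                        literal_lt: bool = False) -> LRPairGraph:
    """Graph over the top-N pairs by total interaction probability.

    Nodes are the pairs with the largest sum of interaction probability over
    all (source, target) cluster combinations (ties by pair index, node order
    by descending score).  Edges connect pairs whose probability profiles
    across the flattened cluster-combination axis have Pearson correlation of
    magnitude >= tau.  ``literal_lt=True`` instead draws an edge when the
    correlation is strictly below tau (the inverted rule, kept selectable).
    """
    prob = np.asarray(prob_tensor.prob, dtype=np.float64)
    pair_names = list(prob_tensor.pair_names)
    if prob.ndim != 3 or prob.shape[2] < 1:
        raise ValueError("probability tensor must be (source, target, pair) with >= 1 pair")
    k1, k2, n_pairs = prob.shape
    if k1 * k2 < 2:
        raise ValueError("need >= 2 (source, target) cluster combinations")
    flat = prob.reshape(k1 * k2, n_pairs).T          # pairs x combinations
    scores = flat.sum(axis=1)
    order = np.argsort(-scores, kind="stable")[: min(top_n, n_pairs)]
    flat = flat[order]
    centered = flat - flat.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered**2).sum(axis=1))
    zero_var = norms == 0
    if zero_var.any():
        warnings.warn(
            f"{int(zero_var.sum())} pair(s) have zero variance across cluster "
            "combinations; their correlations are defined as 0",
            stacklevel=2,
        )
    safe = np.where(zero_var, 1.0, norms)
    corr = (centered @ centered.T) / np.outer(safe, safe)
    corr[zero_var, :] = 0.0
    corr[:, zero_var] = 0.0
    np.fill_diagonal(corr, np.where(zero_var, 0.0, 1.0))
    if literal_lt:
        adj = (corr < tau).astype(np.float64)
    else:
        adj = (np.abs(corr) >= tau).astype(np.float64)
    np.fill_diagonal(adj, 0.0)
    return LRPairGraph(
        pair_names=[pair_names[i] for i in order],
        scores=scores[order],
        correlation=corr,
        adjacency=adj,
        tau=tau,
    )
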