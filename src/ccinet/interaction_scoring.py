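"""Cluster-cluster interaction probabilities and significance labeling.

For an ordered cluster pair (i, j) and a ligand-receptor pair k, the
interaction probability is the product of the source cluster's ligand summary
and the target cluster's receptor summary,

    P_ij^k = L_i * R_j,

where a multi-subunit complex is summarized by the geometric mean of its
subunit summaries — so a single silent subunit inactivates the complex — and
each subunit summary is a 10%-truncated mean over the cluster's cells.

Significance is a majority vote over three statistical scorers applied with a
shared interaction database:

1. a regularized-product score, sqrt(l * r) / (mu + sqrt(l * r)) with mu the
   mean of the processed expression matrix, thresholded at 0.5
   (SingleCellSignalR-style);
2. a label-permutation test on plain mean products (CellPhoneDB-style),
   p <= 0.01;
3. a label-permutation test on truncated mean products (CellChat-style),
   p <= 0.01.

Each permutation test uses the add-one estimator
p = (1 + #{permuted >= observed}) / (1 + n_perm), so p is never zero and lies
in [1/(n_perm+1), 1].  An interaction is significant when at least two
scorers pass.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .lridb import LRIDBTable
from .preprocessing import ClusterLabels, EmptyResultError, ExpressionMatrix

logger = logging.getLogger(__name__)

STATISTICS = ("mean-product", "truncated-mean-product")


def complex_expression(subunit_summaries) -> float:
    """Geometric mean of per-subunit expression summaries (zero if any is zero)."""
    v = np.asarray(subunit_summaries, dtype=np.float64).ravel()
    if v.size == 0:
        raise ValueError("complex_expression of empty subunit list")
    if (v < 0).any():
        raise ValueError("subunit summaries must be non-negative")
    if (v == 0).any():
        return 0.0
    if v.size == 1:
        return float(v[0])
    return float(np.exp(np.log(v).mean()))


def interaction_probability(L_i: float, R_j: float) -> float:
    """Product of ligand and receptor cluster summaries."""
    if L_i < 0 or R_j < 0:
        raise ValueError("summaries must be non-negative")
    return float(L_i * R_j)


def lrscore(l: float, r: float, mu: float) -> float:
    """Regularized product score sqrt(l*r) / (mu + sqrt(l*r)), in [0, 1)."""
    if mu <= 0:
        raise ValueError("mu must be positive")
    if l < 0 or r < 0:
        raise ValueError("expression summaries must be non-negative")
    root = math.sqrt(l * r)
    return root / (mu + root)


def majority_vote(votes) -> bool:
    """True iff at least 2 of exactly 3 boolean votes are true."""
    votes = list(votes)
    if len(votes) != 3:
        raise ValueError(f"expected exactly 3 votes, got {len(votes)}")
    return sum(bool(v) for v in votes) >= 2


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def _cluster_summaries(V: np.ndarray, labels: np.ndarray, n_clusters: int,
                       trunc: float) -> tuple[np.ndarray, np.ndarray]:
    """Per (gene, cluster) plain and truncated means.  V is genes x cells."""
    g = V.shape[0]
    mean = np.empty((g, n_clusters))
    tmean = np.empty((g, n_clusters))
    for c in range(n_clusters):
        block = V[:, labels == c]
        n = block.shape[1]
        mean[:, c] = block.mean(axis=1)
        k = math.floor(trunc * n)
        if k == 0:
            tmean[:, c] = mean[:, c]
        else:
            s = np.sort(block, axis=1)
            tmean[:, c] = s[:, k:n - k].mean(axis=1)
    return mean, tmean


def _complex_rows(summary: np.ndarray, rows: list[int]) -> np.ndarray:
    """Geometric mean across the given gene rows, per cluster (zeros propagate)."""
    block = summary[rows]                      # (m, n_clusters)
    if block.shape[0] == 1:
        return block[0].copy()  # exact: no log/exp round-trip
    with np.errstate(divide="ignore"):
        logs = np.where(block > 0, np.log(np.maximum(block, 1e-300)), -np.inf)
    out = np.exp(logs.mean(axis=0))
    out[(block == 0).any(axis=0)] = 0.0
    return out


def permutation_pvalue(X: ExpressionMatrix, labels: ClusterLabels, pair,
                       source: int, target: int,
                       statistic: str = "mean-product",
                       n_perm: int = 1000, seed: int = 0,
                       trunc: float = 0.10) -> float:
    """Label-permutation p-value for one (source, target, pair) triple.

    The statistic is the product of the source cluster's complex-ligand
    summary and the target cluster's complex-receptor summary, with summaries
    either plain means or ``trunc``-truncated means.  Add-one estimator.
    """
    if statistic not in STATISTICS:
        raise ValueError(f"unknown statistic {statistic!r}; expected one of {STATISTICS}")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if labels.n_clusters < 2:
        raise ValueError("permutation test needs at least 2 clusters")
    lig_rows = list(X.gene_index(pair.ligand_subunits))
    rec_rows = list(X.gene_index(pair.receptor_subunits))
    V = X.values[lig_rows + rec_rows]
    li = list(range(len(lig_rows)))
    ri = list(range(len(lig_rows), V.shape[0]))
    use_trunc = statistic == "truncated-mean-product"

    def stat(lab: np.ndarray) -> float:
        mean, tmean = _cluster_summaries(V, lab, labels.n_clusters, trunc)
        s = tmean if use_trunc else mean
        return _complex_rows(s, li)[source] * _complex_rows(s, ri)[target]

    observed = stat(labels.labels)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        hits += stat(rng.permutation(labels.labels)) >= observed
    return (1 + hits) / (1 + n_perm)


@dataclass
class ProbabilityTensor:
    """Interaction probabilities only (no significance votes)."""

    prob: np.ndarray       # (k, k, n_pairs)
    pair_names: list
    pairs: list


def probability_tensor(X: ExpressionMatrix, labels: ClusterLabels, lridb: LRIDBTable,
                       trunc: float = 0.10) -> ProbabilityTensor:
    """Product of truncated-mean complex summaries for every (i, j, pair)."""
    if len(lridb.pairs) == 0:
        raise EmptyResultError("no ligand-receptor pairs to score")
    genes = sorted({g for p in lridb.pairs for g in p.genes})
    gene_row = {g: i for i, g in enumerate(genes)}
    V = X.values[X.gene_index(genes)]
    _, tmean = _cluster_summaries(V, labels.labels, labels.n_clusters, trunc)
    L = np.stack([_complex_rows(tmean, [gene_row[g] for g in p.ligand_subunits])
                  for p in lridb.pairs])
    R = np.stack([_complex_rows(tmean, [gene_row[g] for g in p.receptor_subunits])
                  for p in lridb.pairs])
    return ProbabilityTensor(np.einsum("pi,pj->ijp", L, R),
                             [p.name for p in lridb.pairs], list(lridb.pairs))


# ---------------------------------------------------------------------------
# full labeling
# ---------------------------------------------------------------------------

@dataclass
class InteractionTensor:
    """Scores and votes for every (source cluster, target cluster, pair)."""

    prob: np.ndarray          # (k, k, n_pairs) interaction probabilities
    lrscore: np.ndarray       # scorer 1 values
    pval_mean: np.ndarray     # scorer 2 p-values
    pval_trunc: np.ndarray    # scorer 3 p-values
    votes: np.ndarray         # int counts in 0..3
    significant: np.ndarray   # votes >= 2
    pair_names: list
    pairs: list               # the LigandReceptorPair records, node order

    @property
    def n_clusters(self) -> int:
        return self.prob.shape[0]

    def to_frame(self) -> pd.DataFrame:
        k, _, p = self.prob.shape
        src, tgt, pk = np.meshgrid(np.arange(k), np.arange(k), np.arange(p), indexing="ij")
        return pd.DataFrame({
            "source_cluster": src.ravel(),
            "target_cluster": tgt.ravel(),
            "ligand": ["+".join(self.pairs[i].ligand_subunits) for i in pk.ravel()],
            "receptor": ["+".join(self.pairs[i].receptor_subunits) for i in pk.ravel()],
            "probability": self.prob.ravel(),
            "lrscore": self.lrscore.ravel(),
            "pval_mean": self.pval_mean.ravel(),
            "pval_trunc": self.pval_trunc.ravel(),
            "votes": self.votes.ravel(),
            "significant": self.significant.ravel(),
        })


def label_significant(X: ExpressionMatrix, labels: ClusterLabels, lridb: LRIDBTable,
                      lrscore_threshold: float = 0.5, pval_threshold: float = 0.01,
                      n_perm: int = 1000, seed: int = 0,
                      trunc: float = 0.10) -> InteractionTensor:
    """Score every (source, target, pair) and label significance by majority vote.

    ``lridb`` must already be restricted to genes present in ``X``.  Both
    permutation scorers share the same label permutations, drawn from ``seed``.
    """
    if len(lridb.pairs) == 0:
        raise EmptyResultError("no ligand-receptor pairs to score")
    missing = lridb.gene_universe - set(X.gene_names)
    if missing:
        raise ValueError(
            f"lridb contains genes absent from the matrix (filter first): {sorted(missing)[:5]}"
        )
    if len(labels) != X.n_cells:
        raise ValueError("labels length does not match cell count")
    k = labels.n_clusters
    pairs = lridb.pairs
    n_pairs = len(pairs)

    genes = sorted({g for p in pairs for g in p.genes})
    gene_row = {g: i for i, g in enumerate(genes)}
    V = X.values[X.gene_index(genes)]
    lig_rows = [[gene_row[g] for g in p.ligand_subunits] for p in pairs]
    rec_rows = [[gene_row[g] for g in p.receptor_subunits] for p in pairs]

    def pair_products(lab: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(k, k, n_pairs) mean- and truncated-mean products for one labeling."""
        mean, tmean = _cluster_summaries(V, lab, k, trunc)
        out = []
        for s in (mean, tmean):
            L = np.stack([_complex_rows(s, r) for r in lig_rows])   # (p, k)
            R = np.stack([_complex_rows(s, r) for r in rec_rows])
            out.append(np.einsum("pi,pj->ijp", L, R))
        return out[0], out[1]

    obs_mean, obs_trunc = pair_products(labels.labels)

    # scorer 1: regularized product on plain cluster means
    mu = float(X.values.mean())
    if mu <= 0:
        raise ValueError("expression matrix mean must be positive for the LR score")
    mean, _ = _cluster_summaries(V, labels.labels, k, trunc)
    Lm = np.stack([_complex_rows(mean, r) for r in lig_rows])
    Rm = np.stack([_complex_rows(mean, r) for r in rec_rows])
    root = np.sqrt(np.einsum("pi,pj->ijp", Lm, Rm))
    score1 = root / (mu + root)

    rng = np.random.default_rng(seed)
    hits_mean = np.zeros_like(obs_mean, dtype=np.int64)
    hits_trunc = np.zeros_like(obs_trunc, dtype=np.int64)
    for _ in range(n_perm):
        perm = rng.permutation(labels.labels)
        pm, pt = pair_products(perm)
        hits_mean += pm >= obs_mean
        hits_trunc += pt >= obs_trunc
    pval_mean = (1 + hits_mean) / (1 + n_perm)
    pval_trunc = (1 + hits_trunc) / (1 + n_perm)

    votes = (
        (score1 >= lrscore_threshold).astype(int)
        + (pval_mean <= pval_threshold).astype(int)
        + (pval_trunc <= pval_threshold).astype(int)
    )
    logger.info(
        "labeled %d significant of %d (cluster pair, LR pair) combinations",
        int((votes >= 2).sum()), votes.size,
    )
    return InteractionTensor(
        prob=obs_trunc,
        lrscore=score1,
        pval_mean=pval_mean,
        pval_trunc=pval_trunc,
        votes=votes,
        significant=votes >= 2,
        pair_names=[p.name for p in pairs],
        pairs=list(pairs),
    )
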