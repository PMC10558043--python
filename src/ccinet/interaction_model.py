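"""Supervised cell-cell interaction classifier: ResNet + pair-graph GCN.

Each ordered cluster pair (source, target) is one training sample.  Its
feature matrix stacks, per ligand-receptor pair, a ligand block — per-cell
complex-ligand expression over the source cluster's cells, reduced to ``d``
components by truncated SVD — concatenated with the matching receptor block
over the target cluster's cells.  Multi-subunit complexes are collapsed per
cell by the geometric mean of their subunits before reduction.

A residual MLP maps each pair's 2d-dimensional feature row to an embedding; a
two-layer GCN propagates learned node embeddings over the thresholded
pair-correlation graph.  The two branch outputs are combined by a row-wise dot
product, passed through a final fully connected layer, and squashed by a
sigmoid into per-pair probabilities.  Training minimizes the focal loss

    L = -(1 - y')^gamma * log(y')   if y = 1
    L = -(y')^gamma * log(1 - y')   if y = 0

under k-fold cross-validation stratified by each sample's positive-label
density.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import nnet
from .graphs import LRPairGraph, normalize_adjacency
from .metrics import ConfusionCounts, UndefinedMetricError, confusion_metrics, roc_auc
from .preprocessing import ClusterLabels, ExpressionMatrix

logger = logging.getLogger(__name__)

PROB_CLAMP = 1e-7


@dataclass
class CCIFeatureSet:
    """Per-cluster-pair feature matrices and per-pair significance labels."""

    features: np.ndarray            # (n_samples, n_pairs, 2d)
    y: np.ndarray | None            # (n_samples, n_pairs) binary, or None
    sample_pairs: list              # ordered (source, target) per sample
    pair_names: list
    d: int

    def __post_init__(self):
        if self.features.ndim != 3:
            raise ValueError("features must be (samples, pairs, 2d)")
        if self.y is not None:
            self.y = np.asarray(self.y, dtype=np.float64)
            if self.y.shape != self.features.shape[:2]:
                raise ValueError("label shape does not match features")
            if not np.isin(self.y, (0.0, 1.0)).all():
                raise ValueError("labels must be binary")

    @property
    def n_samples(self) -> int:
        return self.features.shape[0]

    @property
    def n_pairs(self) -> int:
        return self.features.shape[1]


def _per_cell_complex(X: ExpressionMatrix, subunit_rows: list[np.ndarray],
                      cells: np.ndarray) -> np.ndarray:
    """(n_pairs, n_cells) per-cell geometric-mean complex expression."""
    out = np.empty((len(subunit_rows), int(cells.sum())))
    V = X.values[:, cells]
    for i, rows in enumerate(subunit_rows):
        block = V[rows]
        if block.shape[0] == 1:
            out[i] = block[0]
            continue
        with np.errstate(divide="ignore"):
            logs = np.where(block > 0, np.log(np.maximum(block, 1e-300)), -np.inf)
        g = np.exp(logs.mean(axis=0))
        g[(block == 0).any(axis=0)] = 0.0
        out[i] = g
    return out


def _svd_reduce(block: np.ndarray, d: int) -> np.ndarray:
    """Truncated SVD of a (pairs x cells) block to (pairs x d).

    Deterministic sign convention: each component's largest-magnitude cell
    loading is made positive.  Rank-deficient blocks are zero-padded to d.
    """
    U, S, Vt = np.linalg.svd(block, full_matrices=False)
    tol = S.max(initial=0.0) * max(block.shape) * np.finfo(float).eps
    rank = int((S > tol).sum())
    r = min(d, rank)
    for c in range(r):
        j = np.argmax(np.abs(Vt[c]))
        if Vt[c, j] < 0:
            Vt[c] = -Vt[c]
            U[:, c] = -U[:, c]
    out = np.zeros((block.shape[0], d))
    out[:, :r] = U[:, :r] * S[:r]
    return out


def build_cci_features(X: ExpressionMatrix, labels: ClusterLabels, pairs,
                       d: int = 64, seed: int = 0,
                       significant: np.ndarray | None = None) -> CCIFeatureSet:
    """SVD-reduced ligand/receptor blocks for every ordered cluster pair.

    ``pairs`` is the node list (LigandReceptorPair records) of the pair graph;
    ``significant`` is an optional (k, k, n_pairs) boolean tensor, in the same
    node order, supplying labels.  Deterministic; ``seed`` is kept for
    interface stability (the reduction itself is exact).
    """
    if d < 1:
        raise ValueError("d must be >= 1")
    k = labels.n_clusters
    for c in range(k):
        if (labels.labels == c).sum() < 2:
            raise ValueError(f"cluster {c} has fewer than 2 cells")
    lig_rows = [X.gene_index(p.ligand_subunits) for p in pairs]
    rec_rows = [X.gene_index(p.receptor_subunits) for p in pairs]
    lig_feats = []
    rec_feats = []
    for c in range(k):
        cells = labels.labels == c
        lig_feats.append(_svd_reduce(_per_cell_complex(X, lig_rows, cells), d))
        rec_feats.append(_svd_reduce(_per_cell_complex(X, rec_rows, cells), d))
    samples = [(i, j) for i in range(k) for j in range(k)]
    features = np.stack(
        [np.hstack([lig_feats[i], rec_feats[j]]) for i, j in samples]
    )
    y = None
    if significant is not None:
        significant = np.asarray(significant)
        if significant.shape != (k, k, len(pairs)):
            raise ValueError("significance tensor shape mismatch")
        y = np.stack([significant[i, j].astype(np.float64) for i, j in samples])
    return CCIFeatureSet(features, y, samples, [getattr(p, "name", str(p)) for p in pairs], d)


@dataclass(frozen=True)
class FocalLossConfig:
    gamma: float = 2.0

    def __post_init__(self):
        if not np.isfinite(self.gamma) or self.gamma < 0:
            raise ValueError("gamma must be finite and >= 0")


def focal_loss(y, y_prime, gamma: float = 2.0) -> float:
    """Mean focal loss over elements; probabilities clamped to [1e-7, 1-1e-7]."""
    y = np.asarray(y, dtype=np.float64)
    p = np.clip(np.asarray(y_prime, dtype=np.float64), PROB_CLAMP, 1.0 - PROB_CLAMP)
    if y.shape != p.shape:
        raise ValueError("shape mismatch")
    loss = np.where(y == 1.0, -((1.0 - p) ** gamma) * np.log(p),
                    -(p**gamma) * np.log(1.0 - p))
    return float(loss.mean())


class InteractionModel:
    """ResNet branch + pair-graph GCN branch fused by row-wise dot product."""

    def __init__(self, lr_graph: LRPairGraph, feature_dim: int, seed: int = 0,
                 width: int = 128, n_blocks: int = 3, embed_dim: int = 32,
                 gcn_layers: int = 2, node_init: np.ndarray | None = None):
        rng = np.random.default_rng(seed)
        self.n_pairs = lr_graph.n_nodes
        self.A = normalize_adjacency(lr_graph.adjacency)
        self.inp = nnet.Dense(feature_dim, width, rng)
        self.blocks = [
            (nnet.Dense(width, width, rng), nnet.Dense(width, width, rng))
            for _ in range(n_blocks)
        ]
        self.out = nnet.Dense(width, embed_dim, rng)
        if node_init is None:
            # identical embeddings: the branch starts as one shared predictor
            # and only differentiates nodes where the labels warrant it
            node_init = np.full((self.n_pairs, embed_dim), 0.1)
        elif node_init.shape[1] != embed_dim:
            raise ValueError("node_init dim mismatch")
        self.node_embed = nnet.Tensor(node_init.copy(), requires_grad=True)
        self.gcn = [nnet.Dense(embed_dim, embed_dim, rng) for _ in range(gcn_layers)]
        self.fc = nnet.Dense(self.n_pairs, self.n_pairs, rng)
        # start the mixing layer near the identity so the branch dot product
        # reaches the output unscrambled at initialization
        self.fc.W.data *= 0.05
        self.fc.W.data += np.eye(self.n_pairs)
        # feature standardization (set from the training fold)
        self.feat_mean = np.zeros(feature_dim)
        self.feat_std = np.ones(feature_dim)

    def set_standardization(self, features: np.ndarray) -> None:
        """Fit per-column z-scoring on (n_samples, n_pairs, 2d) training data."""
        flat = features.reshape(-1, features.shape[2])
        self.feat_mean = flat.mean(axis=0)
        self.feat_std = np.where(flat.std(axis=0) > 0, flat.std(axis=0), 1.0)

    @property
    def params(self) -> list[nnet.Tensor]:
        out = self.inp.params + self.out.params + [self.node_embed] + self.fc.params
        for d1, d2 in self.blocks:
            out += d1.params + d2.params
        for l in self.gcn:
            out += l.params
        return out

    def _resnet(self, x: nnet.Tensor) -> nnet.Tensor:
        h = nnet.relu(self.inp(x))
        for d1, d2 in self.blocks:
            h = nnet.relu(nnet.add(h, d2(nnet.relu(d1(h)))))
        return self.out(h)

    def _gcn_nodes(self) -> nnet.Tensor:
        z = self.node_embed
        for i, layer in enumerate(self.gcn):
            pre = nnet.matmul(nnet.spmm(self.A, z), layer.W)
            pre = nnet.add(pre, layer.b)
            z = pre if i == len(self.gcn) - 1 else nnet.relu(pre)
        return z

    def forward_t(self, features: np.ndarray) -> nnet.Tensor:
        """(n_samples, n_pairs, 2d) -> (n_samples, n_pairs) probability tensor."""
        n_samples, n_pairs, fdim = features.shape
        if n_pairs != self.n_pairs:
            raise ValueError(
                f"feature pair count {n_pairs} does not match graph nodes {self.n_pairs}"
            )
        flat = (features.reshape(n_samples * n_pairs, fdim) - self.feat_mean) / self.feat_std
        x = nnet.Tensor(flat)
        res = self._resnet(x)                                 # (N, f)
        gcn = nnet.repeat0(self._gcn_nodes(), n_samples)      # (N, f)
        dot = nnet.tsum(nnet.mul(res, gcn), axis=1, keepdims=True)
        logits = self.fc(nnet.reshape(dot, (n_samples, n_pairs)))
        return nnet.sigmoid(logits)

    def forward(self, features: np.ndarray) -> np.ndarray:
        features = np.asarray(features, dtype=np.float64)
        squeeze = features.ndim == 2
        if squeeze:
            features = features[None]
        probs = self.forward_t(features).data
        return probs[0] if squeeze else probs

    # -- persistence -------------------------------------------------------
    def save(self, path) -> None:
        np.savez(path, feat_mean=self.feat_mean, feat_std=self.feat_std,
                 **{f"p{i}": p.data for i, p in enumerate(self.params)})

    def load(self, path) -> None:
        with np.load(path) as z:
            self.feat_mean = z["feat_mean"]
            self.feat_std = z["feat_std"]
            for i, p in enumerate(self.params):
                p.data[...] = z[f"p{i}"]


def _focal_loss_t(y: np.ndarray, probs: nnet.Tensor, gamma: float) -> nnet.Tensor:
    p = nnet.clip(probs, PROB_CLAMP, 1.0 - PROB_CLAMP)
    one = nnet.Tensor(1.0)
    pos = nnet.mul(nnet.power(nnet.sub(one, p), gamma), nnet.log(p))
    neg = nnet.mul(nnet.power(p, gamma), nnet.log(nnet.sub(one, p)))
    ym = nnet.Tensor(y)
    per = nnet.add(nnet.mul(ym, pos), nnet.mul(nnet.sub(one, ym), neg))
    return nnet.mul(nnet.Tensor(-1.0), nnet.tmean(per))


def _stratified_folds(y: np.ndarray, folds: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Deal samples into folds round-robin by descending positive density."""
    density = y.mean(axis=1)
    order = np.argsort(-density, kind="stable")
    assignment = np.empty(len(density), dtype=int)
    offset = int(rng.integers(folds))
    for rank, idx in enumerate(order):
        assignment[idx] = (rank + offset) % folds
    return [np.flatnonzero(assignment == f) for f in range(folds)]


def _fold_metrics(y_true: np.ndarray, probs: np.ndarray, threshold: float) -> dict:
    calls = probs >= threshold
    m = confusion_metrics(ConfusionCounts.from_calls(y_true.ravel(), calls.ravel()))
    try:
        m["AUC"] = roc_auc(probs.ravel(), y_true.ravel())
    except UndefinedMetricError:
        warnings.warn("fold contains a single class; AUC undefined", stacklevel=2)
        m["AUC"] = None
    return m


def train_interaction_model(
    featureset: CCIFeatureSet,
    lr_graph: LRPairGraph,
    gamma: float = 2.0,
    folds: int = 5,
    repeats: int = 1,
    seed: int = 0,
    epochs: int = 150,
    lr: float = 1e-3,
    threshold: float = 0.5,
    pair_shrink: float = 0.005,
) -> tuple[list[InteractionModel], list[dict]]:
    """K-fold cross-validated training; returns per-fold models and metrics.

    Samples (ordered cluster pairs) are split into ``folds`` stratified by
    positive-label density; each fold's model minimizes the focal loss on the
    remaining samples and is evaluated on the held-out fold (recall,
    precision, ACC, F1, AUC).  ``repeats`` re-runs the whole procedure with
    fresh splits; metrics of every fold of every repeat are returned in order.
    """
    if featureset.y is None:
        raise ValueError("featureset has no labels; build with a significance tensor")
    if featureset.n_samples < folds:
        raise ValueError(f"need at least {folds} samples for {folds}-fold CV")
    FocalLossConfig(gamma)
    # node embeddings start from the pairs' probability profiles, via scores
    node_init_scale = lr_graph.scores / max(lr_graph.scores.max(), 1e-12)
    models: list[InteractionModel] = []
    all_metrics: list[dict] = []
    for rep in range(repeats):
        rng = np.random.default_rng(seed + 1000 * rep)
        fold_idx = _stratified_folds(featureset.y, folds, rng)
        for f, test_idx in enumerate(fold_idx):
            train_idx = np.setdiff1d(np.arange(featureset.n_samples), test_idx)
            model = InteractionModel(
                lr_graph, featureset.features.shape[2],
                seed=seed + 1000 * rep + f,
            )
            model.node_embed.data += node_init_scale[:, None] * 0.1
            opt = nnet.Adam(model.params, lr=lr)
            Xtr = featureset.features[train_idx]
            ytr = featureset.y[train_idx]
            model.set_standardization(Xtr)
            eye = np.eye(model.n_pairs, dtype=bool)
            for _ in range(epochs):
                opt.zero_grad()
                probs = model.forward_t(Xtr)
                loss = _focal_loss_t(ytr, probs, gamma)
                loss.backward()
                opt.step()
                # shrink pair-identity channels toward the shared predictor:
                # deviations must be continually re-earned by the labels, so
                # pairs without informative training labels fall back to the
                # shared row-wise rule instead of drifting
                ne = model.node_embed.data
                ne -= pair_shrink * (ne - ne.mean(axis=0, keepdims=True))
                model.fc.W.data[~eye] *= 1.0 - pair_shrink
                model.fc.b.data *= 1.0 - pair_shrink
            test_probs = model.forward(featureset.features[test_idx])
            all_metrics.append(_fold_metrics(featureset.y[test_idx], test_probs, threshold))
            models.append(model)
    return models, all_metrics


def predict_interactions(model: InteractionModel, featureset: CCIFeatureSet,
                         threshold: float = 0.5) -> pd.DataFrame:
    """Long-format per (source, target, pair) probabilities and binary calls.

    A probability exactly at the threshold is a positive call.
    """
    probs = model.forward(featureset.features)
    rows = []
    for s_idx, (i, j) in enumerate(featureset.sample_pairs):
        for p_idx, name in enumerate(featureset.pair_names):
            lig, _, rec = name.partition("->")
            rows.append({
                "source_cluster": i, "target_cluster": j,
                "ligand": lig, "receptor": rec,
                "probability": probs[s_idx, p_idx],
                "call": bool(probs[s_idx, p_idx] >= threshold),
            })
    return pd.DataFrame(rows)
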