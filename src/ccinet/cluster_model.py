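"""Joint autoencoder + graph-convolutional deep embedded clustering.

A fully connected autoencoder learns a low-dimensional embedding of the
(cells x genes) expression matrix by minimizing reconstruction error.  A GCN
branch propagates representations over the normalized KNN cell-graph
adjacency; at every depth the two branches are fused,
``(1 - eps) * Z + eps * H``, so the graph branch sees both topology and the
autoencoder's features.  Cluster membership is a Student's-t kernel between
the embedding and trainable cluster centers (soft assignment Q); a sharpened
target distribution P — Q squared and normalized by soft cluster frequencies —
self-trains both Q and the GCN's own assignment distribution Z through KL
divergence terms:

    L = alpha * KL(P || Q) + beta * KL(P || Z) + L_reconstruction

Training is full batch: pretrain the autoencoder alone, initialize centers by
k-means on the pretrained embedding, then descend the joint loss with P
refreshed on a fixed interval.  Hard labels are the row argmax of Q.

All public operations are plain-numpy; training runs on the in-package
autodiff engine (:mod:`ccinet.nnet`) and every source of randomness derives
from one user seed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from . import nnet
from .graphs import CellGraph, normalize_adjacency
from .preprocessing import ClusterLabels

logger = logging.getLogger(__name__)

LOG_FLOOR = 1e-12  # numerical floor inside logarithms


class DivergenceError(RuntimeError):
    """Raised when training produces a non-finite loss."""


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass
class AEParams:
    """Encoder/decoder weights of the autoencoder (hidden ReLU, linear output)."""

    enc_W: list
    enc_b: list
    dec_W: list
    dec_b: list

    def __post_init__(self):
        dims = self.dims
        for W_list, b_list, tag in ((self.enc_W, self.enc_b, "encoder"),
                                    (self.dec_W, self.dec_b, "decoder")):
            if len(W_list) != len(b_list):
                raise ValueError(f"{tag} weight/bias counts differ")
            for i in range(len(W_list) - 1):
                if W_list[i].shape[1] != W_list[i + 1].shape[0]:
                    raise ValueError(f"{tag} layer dims incompatible at layer {i}")
        if self.enc_W[-1].shape[1] != self.dec_W[0].shape[0]:
            raise ValueError("embedding dim does not match decoder input")

    @property
    def dims(self) -> list[int]:
        return [self.enc_W[0].shape[0]] + [W.shape[1] for W in self.enc_W]

    @property
    def embedding_dim(self) -> int:
        return self.enc_W[-1].shape[1]

    def save(self, path) -> None:
        """Checkpoint to a .npz container."""
        arrays = {}
        for tag, group in (("eW", self.enc_W), ("eb", self.enc_b),
                           ("dW", self.dec_W), ("db", self.dec_b)):
            for i, arr in enumerate(group):
                arrays[f"{tag}{i}"] = arr
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "AEParams":
        with np.load(path) as z:
            def group(tag):
                keys = sorted((k for k in z.files if k.startswith(tag)),
                              key=lambda k: int(k[len(tag):]))
                return [z[k] for k in keys]
            return cls(enc_W=group("eW"), enc_b=group("eb"),
                       dec_W=group("dW"), dec_b=group("db"))


@dataclass
class ClusterCenters:
    """Cluster center vectors and the Student's-t degrees of freedom."""

    mu: np.ndarray
    v: float = 1.0

    def __post_init__(self):
        self.mu = np.asarray(self.mu, dtype=np.float64)
        if self.mu.ndim != 2 or self.mu.shape[0] < 2:
            raise ValueError("need at least 2 cluster centers")
        if self.v <= 0:
            raise ValueError("degrees of freedom must be positive")


@dataclass
class SoftAssignment:
    """Row-stochastic cells x clusters soft membership matrix Q."""

    Q: np.ndarray

    def __post_init__(self):
        self.Q = np.asarray(self.Q, dtype=np.float64)
        if (self.Q <= 0).any() or (self.Q > 1).any():
            raise ValueError("soft assignments must lie in (0, 1]")
        if not np.allclose(self.Q.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("soft assignment rows must sum to 1")

    def hard_labels(self) -> np.ndarray:
        return self.Q.argmax(axis=1)


@dataclass
class TargetDistribution:
    """Sharpened self-training target P with soft cluster frequencies f."""

    P: np.ndarray
    f: np.ndarray

    def __post_init__(self):
        self.P = np.asarray(self.P, dtype=np.float64)
        self.f = np.asarray(self.f, dtype=np.float64)
        if not np.allclose(self.P.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("target distribution rows must sum to 1")


@dataclass(frozen=True)
class LossWeights:
    """Weights of the joint loss and the branch-fusion coefficient."""

    alpha: float = 1e-4   # KL(P || Q)
    beta: float = 1e-3    # KL(P || Z)
    epsilon: float = 0.5  # fusion: (1 - eps) * GCN + eps * AE

    def __post_init__(self):
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be non-negative")
        if not (0.0 <= self.epsilon <= 1.0):
            raise ValueError("epsilon must lie in [0, 1]")


# ---------------------------------------------------------------------------
# operations (plain numpy)
# ---------------------------------------------------------------------------

def _relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def ae_forward(X: np.ndarray, params: AEParams) -> tuple[list[np.ndarray], np.ndarray]:
    """Forward pass: returns encoder representations [H(0)..H(L)] and X-hat.

    Hidden layers use ReLU; the encoder output and decoder output are linear.
    ``X`` is cells x genes.
    """
    X = np.asarray(X, dtype=np.float64)
    if X.shape[1] != params.enc_W[0].shape[0]:
        raise ValueError(
            f"input dim {X.shape[1]} does not match encoder ({params.enc_W[0].shape[0]})"
        )
    H = [X]
    n_enc = len(params.enc_W)
    for l, (W, b) in enumerate(zip(params.enc_W, params.enc_b)):
        pre = H[-1] @ W + b
        H.append(pre if l == n_enc - 1 else _relu(pre))
    out = H[-1]
    n_dec = len(params.dec_W)
    for l, (W, b) in enumerate(zip(params.dec_W, params.dec_b)):
        pre = out @ W + b
        out = pre if l == n_dec - 1 else _relu(pre)
    return H, out


def reconstruction_loss(X: np.ndarray, X_hat: np.ndarray) -> float:
    """Mean squared Frobenius reconstruction error, ||X - X-hat||_F^2 / (2N)."""
    X = np.asarray(X, dtype=np.float64)
    X_hat = np.asarray(X_hat, dtype=np.float64)
    if X.shape != X_hat.shape:
        raise ValueError("X and X_hat shapes differ")
    n = X.shape[0]
    return float(np.sum((X - X_hat) ** 2) / (2.0 * n))


def combine_representations(Z: np.ndarray, H: np.ndarray, epsilon: float = 0.5) -> np.ndarray:
    """Fuse GCN and AE representations: (1 - eps) * Z + eps * H."""
    Z = np.asarray(Z, dtype=np.float64)
    H = np.asarray(H, dtype=np.float64)
    if Z.shape != H.shape:
        raise ValueError("Z and H shapes differ")
    return (1.0 - epsilon) * Z + epsilon * H


def gcn_layer(Z_prev: np.ndarray, A_norm, W: np.ndarray, activation=_relu) -> np.ndarray:
    """One graph convolution: activation(A_norm @ Z_prev @ W)."""
    out = A_norm @ np.asarray(Z_prev, dtype=np.float64) @ np.asarray(W, dtype=np.float64)
    return activation(np.asarray(out)) if activation is not None else np.asarray(out)


def soft_assign(embedding: np.ndarray, centers: ClusterCenters) -> SoftAssignment:
    """Student's-t kernel soft assignment of cells to cluster centers."""
    H = np.asarray(embedding, dtype=np.float64)
    mu, v = centers.mu, centers.v
    if H.shape[1] != mu.shape[1]:
        raise ValueError("embedding dim does not match centers")
    sqd = ((H[:, None, :] - mu[None, :, :]) ** 2).sum(axis=2)
    kernel = (1.0 + sqd / v) ** (-(v + 1.0) / 2.0)
    return SoftAssignment(kernel / kernel.sum(axis=1, keepdims=True))


def target_distribution(Q) -> TargetDistribution:
    """Sharpen Q: p_ij = (q_ij^2 / f_j) / sum_j' (q_ij'^2 / f_j'), f_j = sum_i q_ij."""
    Qa = Q.Q if isinstance(Q, SoftAssignment) else np.asarray(Q, dtype=np.float64)
    f = Qa.sum(axis=0)
    zero = f <= 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} empty soft cluster(s) excluded from the target distribution",
            stacklevel=2,
        )
    weight = np.where(zero[None, :], 0.0, Qa**2 / np.where(zero, 1.0, f)[None, :])
    return TargetDistribution(weight / weight.sum(axis=1, keepdims=True), f)


def kl_loss(P, Q, floor: float = LOG_FLOOR) -> float:
    """KL(P || Q) = sum_ij p_ij log(p_ij / q_ij), with q clamped at ``floor``."""
    Pa = P.P if isinstance(P, TargetDistribution) else np.asarray(P, dtype=np.float64)
    Qa = Q.Q if isinstance(Q, SoftAssignment) else np.asarray(Q, dtype=np.float64)
    if Pa.shape != Qa.shape:
        raise ValueError("P and Q shapes differ")
    if (Qa < floor).any():
        logger.debug("kl_loss clamped %d entries at the %g floor", int((Qa < floor).sum()), floor)
    Qc = np.maximum(Qa, floor)
    mask = Pa > 0
    return float(np.sum(Pa[mask] * np.log(Pa[mask] / Qc[mask])))


def total_loss(l_clu: float, l_gcn: float, l_res: float,
               weights: LossWeights = LossWeights()) -> float:
    """Joint objective alpha * L_clu + beta * L_gcn + L_res."""
    for v in (l_clu, l_gcn, l_res):
        if not np.isfinite(v):
            raise ValueError("component losses must be finite")
    return weights.alpha * l_clu + weights.beta * l_gcn + l_res


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

DEFAULT_HIDDEN = (256, 128, 32)


class _AENet:
    """Autoencoder as autodiff layers (hidden ReLU, linear outputs)."""

    def __init__(self, n_in: int, hidden: tuple[int, ...], rng: np.random.Generator):
        dims = (n_in,) + tuple(hidden)
        self.enc = [nnet.Dense(dims[i], dims[i + 1], rng) for i in range(len(hidden))]
        rev = dims[::-1]
        self.dec = [nnet.Dense(rev[i], rev[i + 1], rng) for i in range(len(hidden))]

    def encode(self, x: nnet.Tensor) -> list[nnet.Tensor]:
        H = [x]
        for l, layer in enumerate(self.enc):
            pre = layer(H[-1])
            H.append(pre if l == len(self.enc) - 1 else nnet.relu(pre))
        return H

    def decode(self, h: nnet.Tensor) -> nnet.Tensor:
        out = h
        for l, layer in enumerate(self.dec):
            pre = layer(out)
            out = pre if l == len(self.dec) - 1 else nnet.relu(pre)
        return out

    @property
    def params(self) -> list[nnet.Tensor]:
        return [p for layer in self.enc + self.dec for p in layer.params]

    def export(self) -> AEParams:
        return AEParams(
            enc_W=[l.W.data.copy() for l in self.enc],
            enc_b=[l.b.data.copy() for l in self.enc],
            dec_W=[l.W.data.copy() for l in self.dec],
            dec_b=[l.b.data.copy() for l in self.dec],
        )

    def load(self, params: AEParams) -> None:
        for layer, W, b in zip(self.enc, params.enc_W, params.enc_b):
            layer.W.data[...] = W
            layer.b.data[...] = b
        for layer, W, b in zip(self.dec, params.dec_W, params.dec_b):
            layer.W.data[...] = W
            layer.b.data[...] = b


def _recon_loss_t(x: nnet.Tensor, x_hat: nnet.Tensor) -> nnet.Tensor:
    n = x.shape[0]
    diff = nnet.sub(x, x_hat)
    return nnet.div(nnet.tsum(nnet.mul(diff, diff)), nnet.Tensor(2.0 * n))


def pretrain_ae(X: np.ndarray, epochs: int = 80, seed: int = 0,
                hidden: tuple[int, ...] = DEFAULT_HIDDEN, lr: float = 1e-3) -> AEParams:
    """Train the autoencoder alone on the reconstruction objective.

    ``X`` is cells x genes (variable genes selected).  Full-batch Adam;
    deterministic for a fixed seed.  Raises :class:`DivergenceError` if the
    loss leaves the reals.
    """
    X = np.asarray(X, dtype=np.float64)
    rng = np.random.default_rng(seed)
    net = _AENet(X.shape[1], hidden, rng)
    opt = nnet.Adam(net.params, lr=lr)
    x = nnet.Tensor(X)
    for epoch in range(epochs):
        opt.zero_grad()
        H = net.encode(x)
        loss = _recon_loss_t(x, net.decode(H[-1]))
        if not np.isfinite(loss.data):
            raise DivergenceError(f"autoencoder pretraining diverged at epoch {epoch}")
        loss.backward()
        opt.step()
    return net.export()


class _JointNet:
    """Autoencoder fused with a GCN branch, plus trainable cluster centers."""

    def __init__(self, n_in: int, hidden: tuple[int, ...], n_clusters: int,
                 A_norm, rng: np.random.Generator, epsilon: float, v: float):
        self.ae = _AENet(n_in, hidden, rng)
        dims = (n_in,) + tuple(hidden)
        self.gcn = [nnet.Dense(dims[i], dims[i + 1], rng) for i in range(len(hidden))]
        self.gcn_out = nnet.Dense(hidden[-1], n_clusters, rng)
        self.mu = nnet.Tensor(np.zeros((n_clusters, hidden[-1])), requires_grad=True)
        self.A = A_norm
        self.eps = epsilon
        self.v = v

    @property
    def params(self) -> list[nnet.Tensor]:
        return (self.ae.params + [p for l in self.gcn for p in l.params]
                + self.gcn_out.params + [self.mu])

    def forward(self, x: nnet.Tensor):
        """Returns (embedding H(L), X-hat, Q, Z-distribution) as tensors."""
        H = self.ae.encode(x)
        z = x
        for l, layer in enumerate(self.gcn):
            pre = nnet.matmul(nnet.spmm(self.A, z), layer.W)
            pre = nnet.add(pre, layer.b)
            zl = pre if l == len(self.gcn) - 1 else nnet.relu(pre)
            # layer-wise fusion with the matching encoder representation
            z = nnet.add(
                nnet.mul(nnet.Tensor(1.0 - self.eps), zl),
                nnet.mul(nnet.Tensor(self.eps), H[l + 1]),
            )
        logits = nnet.add(nnet.matmul(nnet.spmm(self.A, z), self.gcn_out.W), self.gcn_out.b)
        z_dist = nnet.softmax_rows(logits)
        x_hat = self.ae.decode(H[-1])
        q = self._soft_assign(H[-1])
        return H[-1], x_hat, q, z_dist

    def _soft_assign(self, h: nnet.Tensor) -> nnet.Tensor:
        h_sq = nnet.tsum(nnet.mul(h, h), axis=1, keepdims=True)            # (n, 1)
        mu_sq = nnet.transpose(nnet.tsum(nnet.mul(self.mu, self.mu), axis=1, keepdims=True))
        cross = nnet.matmul(h, nnet.transpose(self.mu))
        sqd = nnet.add(nnet.sub(h_sq, nnet.mul(nnet.Tensor(2.0), cross)), mu_sq)
        sqd = nnet.clip(sqd, 0.0, np.inf)
        kernel = nnet.power(
            nnet.add(nnet.Tensor(1.0), nnet.div(sqd, nnet.Tensor(self.v))),
            -(self.v + 1.0) / 2.0,
        )
        return nnet.div(kernel, nnet.tsum(kernel, axis=1, keepdims=True))


def _kl_t(P: np.ndarray, q: nnet.Tensor) -> nnet.Tensor:
    logp = np.where(P > 0, np.log(np.maximum(P, LOG_FLOOR)), 0.0)
    logq = nnet.log(nnet.clip(q, LOG_FLOOR, np.inf))
    return nnet.tsum(nnet.mul(nnet.Tensor(P), nnet.sub(nnet.Tensor(logp), logq)))


def _kmeans_init(embedding: np.ndarray, n_clusters: int, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """K-means centers on the pretrained embedding; re-seed on empty clusters."""
    for attempt in range(10):
        km = KMeans(n_clusters=n_clusters, n_init=10, random_state=seed + attempt)
        labels = km.fit_predict(embedding)
        if len(np.unique(labels)) == n_clusters:
            return km.cluster_centers_, labels
        logger.warning("k-means produced an empty cluster; re-initializing (attempt %d)", attempt + 1)
    raise RuntimeError("k-means initialization failed to fill all clusters in 10 attempts")


def fit_cluster_model(
    X: np.ndarray,
    graph: CellGraph,
    n_clusters: int,
    weights: LossWeights = LossWeights(),
    seed: int = 0,
    epochs: int = 60,
    pretrain_epochs: int = 80,
    hidden: tuple[int, ...] = DEFAULT_HIDDEN,
    lr: float = 1e-4,
    pretrain_lr: float = 1e-3,
    update_interval: int = 5,
    v: float = 1.0,
    ae_params: AEParams | None = None,
) -> tuple[ClusterLabels, np.ndarray, SoftAssignment]:
    """Train the joint model and return (labels, embedding, soft assignment).

    ``X`` is cells x genes (log-normalized variable genes); ``graph`` the KNN
    cell graph over the same cells.  The autoencoder is pretrained (unless
    ``ae_params`` is given), centers are initialized by k-means on the
    pretrained embedding, and the joint loss is descended full-batch with the
    target distribution refreshed every ``update_interval`` epochs.
    """
    X = np.asarray(X, dtype=np.float64)
    if n_clusters < 2:
        raise ValueError("n_clusters must be >= 2")
    if graph.n_cells != X.shape[0]:
        raise ValueError("graph size does not match number of cells")
    if ae_params is None:
        ae_params = pretrain_ae(X, epochs=pretrain_epochs, seed=seed,
                                hidden=hidden, lr=pretrain_lr)
    rng = np.random.default_rng(seed + 1)
    A_norm = normalize_adjacency(graph.adjacency)
    net = _JointNet(X.shape[1], hidden, n_clusters, A_norm, rng,
                    epsilon=weights.epsilon, v=v)
    net.ae.load(ae_params)

    emb0, _ = ae_forward(X, ae_params)
    centers, _ = _kmeans_init(emb0[-1], n_clusters, seed=seed + 2)
    net.mu.data[...] = centers

    opt = nnet.Adam(net.params, lr=lr)
    x = nnet.Tensor(X)
    P = None
    for epoch in range(epochs):
        opt.zero_grad()
        h, x_hat, q, z_dist = net.forward(x)
        if epoch % update_interval == 0:
            P = target_distribution(q.data).P
        loss = nnet.add(
            nnet.add(
                nnet.mul(nnet.Tensor(weights.alpha), _kl_t(P, q)),
                nnet.mul(nnet.Tensor(weights.beta), _kl_t(P, z_dist)),
            ),
            _recon_loss_t(x, x_hat),
        )
        if not np.isfinite(loss.data):
            raise DivergenceError(f"joint training diverged at epoch {epoch}")
        loss.backward()
        opt.step()

    h, _, q, _ = net.forward(x)
    Q = SoftAssignment(q.data / q.data.sum(axis=1, keepdims=True))
    hard = Q.hard_labels()
    labels, _ = ClusterLabels.from_values(hard)
    if labels.n_clusters < n_clusters:
        logger.info("final assignment uses %d of %d clusters", labels.n_clusters, n_clusters)
    return labels, h.data, Q
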