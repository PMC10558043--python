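"""Focal loss, feature construction, and the ResNet+GCN classifier."""

import numpy as np
import pytest

from ccinet import ClusterLabels, ExpressionMatrix
from ccinet.graphs import LRPairGraph
from ccinet.interaction_model import (
    CCIFeatureSet,
    FocalLossConfig,
    InteractionModel,
    _svd_reduce,
    build_cci_features,
    focal_loss,
    predict_interactions,
    train_interaction_model,
)
from ccinet.lridb import LigandReceptorPair


def _cross_entropy(y, p):
    p = np.clip(p, 1e-7, 1 - 1e-7)
    return float(np.mean(-(y * np.log(p) + (1 - y) * np.log(1 - p))))


class TestFocalLoss:
    def test_gamma_zero_equals_cross_entropy(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 1000).astype(float)
        p = rng.uniform(0.01, 0.99, 1000)
        assert abs(focal_loss(y, p, 0.0) - _cross_entropy(y, p)) <= 1e-10

    def test_hand_value(self):
        assert focal_loss(np.array([1.0]), np.array([0.9]), 2.0) == pytest.approx(
            0.01 * -np.log(0.9), rel=1e-6)
        assert focal_loss(np.array([1.0]), np.array([0.9]), 2.0) == pytest.approx(
            0.0010536, abs=1e-6)

    def test_confident_correct_prediction_vanishes(self):
        assert focal_loss(np.array([1.0]), np.array([1.0 - 1e-9]), 2.0) < 1e-10

    def test_monotone_on_grid(self):
        grid = np.linspace(0.01, 0.99, 50)
        pos = [focal_loss(np.array([1.0]), np.array([p]), 2.0) for p in grid]
        neg = [focal_loss(np.array([0.0]), np.array([p]), 2.0) for p in grid]
        assert (np.diff(pos) <= 1e-12).all()
        assert (np.diff(neg) >= -1e-12).all()

    def test_invalid_gamma(self):
        with pytest.raises(ValueError):
            FocalLossConfig(float("nan"))


class TestSVDReduce:
    def test_rank_one_block_recovered_exactly(self):
        rng = np.random.default_rng(1)
        block = np.outer(rng.normal(size=6), rng.normal(size=10))
        feats = _svd_reduce(block, d=1)
        # one component reconstructs a rank-1 block
        U, S, Vt = np.linalg.svd(block, full_matrices=False)
        recon = feats @ feats.T @ block / (feats**2).sum()
        assert np.linalg.norm(recon - block) / np.linalg.norm(block) <= 1e-6

    def test_rank_deficient_blocks_zero_padded(self):
        block = np.outer([1.0, 2.0], [3.0, 4.0])
        feats = _svd_reduce(block, d=5)
        assert feats.shape == (2, 5)
        assert (feats[:, 1:] == 0).all()

    def test_sign_convention_deterministic(self):
        rng = np.random.default_rng(2)
        block = rng.normal(size=(5, 8))
        np.testing.assert_array_equal(_svd_reduce(block, 3), _svd_reduce(block, 3))


@pytest.fixture(scope="module")
def small_featureset():
    rng = np.random.default_rng(3)
    n_genes, n_cells = 12, 60
    values = rng.poisson(2.0, size=(n_genes, n_cells)).astype(float) + 0.1
    genes = [f"L{i}" for i in range(6)] + [f"R{i}" for i in range(6)]
    X = ExpressionMatrix(values, genes, [f"c{i}" for i in range(n_cells)])
    labels = ClusterLabels(np.repeat([0, 1, 2], 20))
    pairs = [LigandReceptorPair((f"L{i}",), (f"R{i}",), "human") for i in range(5)]
    pairs.append(LigandReceptorPair(("L5",), ("R4", "R5"), "human"))
    sig = rng.random((3, 3, 6)) < 0.3
    fs = build_cci_features(X, labels, pairs, d=4, seed=0, significant=sig)
    return X, labels, pairs, fs


class TestBuildFeatures:
    def test_shapes_and_labels(self, small_featureset):
        _, labels, pairs, fs = small_featureset
        assert fs.features.shape == (9, 6, 8)
        assert fs.y.shape == (9, 6)
        assert fs.sample_pairs == [(i, j) for i in range(3) for j in range(3)]

    def test_zero_subunit_gives_zero_ligand_row(self):
        values = np.ones((3, 20))
        values[1] = 0.0  # second ligand subunit silent everywhere
        X = ExpressionMatrix(values, ["La", "Lb", "R"], [f"c{i}" for i in range(20)])
        labels = ClusterLabels(np.repeat([0, 1], 10))
        pair = LigandReceptorPair(("La", "Lb"), ("R",), "human")
        fs = build_cci_features(X, labels, [pair], d=2, seed=0)
        # ligand half of the feature row is identically zero for every sample
        assert (fs.features[:, 0, :2] == 0).all()

    def test_cell_permutation_leaves_singular_values_unchanged(self, small_featureset):
        X, labels, pairs, _ = small_featureset
        rng = np.random.default_rng(4)
        perm = np.arange(X.n_cells)
        block = labels.labels == 0
        perm[block] = rng.permutation(np.flatnonzero(block))
        Xp = ExpressionMatrix(X.values[:, perm], X.gene_names,
                              [f"p{i}" for i in range(X.n_cells)])
        fs1 = build_cci_features(X, labels, pairs, d=4, seed=0)
        fs2 = build_cci_features(Xp, labels, pairs, d=4, seed=0)
        # singular values = column norms of the reduced block
        np.testing.assert_allclose(
            np.linalg.norm(fs1.features[0, :, :4], axis=0),
            np.linalg.norm(fs2.features[0, :, :4], axis=0), atol=1e-8)

    def test_tiny_cluster_rejected(self):
        X = ExpressionMatrix(np.ones((2, 5)), ["L", "R"], list("abcde"))
        labels = ClusterLabels(np.array([0, 0, 1, 1, 2]), 3)
        pair = LigandReceptorPair(("L",), ("R",), "human")
        with pytest.raises(ValueError, match="cluster 2"):
            build_cci_features(X, labels, [pair], d=2, seed=0)


def _complete_graph(n):
    adj = 1.0 - np.eye(n)
    return LRPairGraph([f"p{i}" for i in range(n)], np.arange(n, 0, -1, dtype=float),
                       np.ones((n, n)), adj, tau=0.95)


class TestForward:
    def test_zero_final_layer_gives_half(self, small_featureset):
        *_, fs = small_featureset
        g = _complete_graph(6)
        model = InteractionModel(g, 8, seed=0)
        model.fc.W.data[...] = 0.0
        model.fc.b.data[...] = 0.0
        probs = model.forward(fs.features[0])
        np.testing.assert_allclose(probs, 0.5)

    def test_outputs_in_unit_interval_and_pure(self, small_featureset):
        *_, fs = small_featureset
        model = InteractionModel(_complete_graph(6), 8, seed=1)
        p1 = model.forward(fs.features)
        p2 = model.forward(fs.features)
        assert ((p1 > 0) & (p1 < 1)).all()
        np.testing.assert_array_equal(p1, p2)

    def test_node_count_mismatch_raises(self, small_featureset):
        *_, fs = small_featureset
        model = InteractionModel(_complete_graph(4), 8, seed=0)
        with pytest.raises(ValueError):
            model.forward(fs.features)

    def test_save_load_round_trip(self, small_featureset, tmp_path):
        *_, fs = small_featureset
        g = _complete_graph(6)
        model = InteractionModel(g, 8, seed=2)
        model.set_standardization(fs.features)
        before = model.forward(fs.features)
        model.save(tmp_path / "m.npz")
        fresh = InteractionModel(g, 8, seed=99)
        fresh.load(tmp_path / "m.npz")
        np.testing.assert_array_equal(before, fresh.forward(fs.features))


class TestTraining:
    @pytest.fixture(scope="class")
    def linear_rule_set(self):
        """Labels determined by one feature column; 4 clusters x 12 pairs."""
        rng = np.random.default_rng(5)
        n_samples, n_pairs, fdim = 16, 12, 10
        features = rng.normal(size=(n_samples, n_pairs, fdim))
        y = (features[:, :, 0] > 0.4).astype(float)
        fs = CCIFeatureSet(features, y, [(i, j) for i in range(4) for j in range(4)],
                           [f"p{i}" for i in range(n_pairs)], d=5)
        return fs, _complete_graph(n_pairs)

    def test_linear_rule_learned(self, linear_rule_set):
        fs, g = linear_rule_set
        _, metrics = train_interaction_model(fs, g, gamma=2.0, folds=5, seed=0,
                                             epochs=120)
        aucs = [m["AUC"] for m in metrics if m["AUC"] is not None]
        assert np.mean(aucs) >= 0.95

    def test_shuffled_labels_near_chance(self, linear_rule_set):
        fs, g = linear_rule_set
        means = []
        for seed in range(5):
            rng = np.random.default_rng(seed + 100)
            y = rng.permutation(fs.y.ravel()).reshape(fs.y.shape)
            shuffled = CCIFeatureSet(fs.features, y, fs.sample_pairs, fs.pair_names, fs.d)
            _, metrics = train_interaction_model(shuffled, g, gamma=2.0, folds=5,
                                                 seed=seed, epochs=60)
            aucs = [m["AUC"] for m in metrics if m["AUC"] is not None]
            means.append(np.mean(aucs))
        assert 0.35 <= np.mean(means) <= 0.65

    def test_training_loss_decreases(self, linear_rule_set):
        from ccinet import nnet
        from ccinet.interaction_model import _focal_loss_t
        fs, g = linear_rule_set
        model = InteractionModel(g, 10, seed=0)
        model.set_standardization(fs.features)
        opt = nnet.Adam(model.params, lr=1e-3)
        losses = []
        for _ in range(60):
            opt.zero_grad()
            loss = _focal_loss_t(fs.y, model.forward_t(fs.features), 2.0)
            loss.backward()
            opt.step()
            losses.append(loss.data.item())
        assert losses[-1] < losses[0]

    def test_deterministic_folds_and_metrics(self, linear_rule_set):
        fs, g = linear_rule_set
        _, m1 = train_interaction_model(fs, g, folds=4, seed=11, epochs=20)
        _, m2 = train_interaction_model(fs, g, folds=4, seed=11, epochs=20)
        assert m1 == m2

    def test_too_few_samples_rejected(self, linear_rule_set):
        fs, g = linear_rule_set
        small = CCIFeatureSet(fs.features[:3], fs.y[:3], fs.sample_pairs[:3],
                              fs.pair_names, fs.d)
        with pytest.raises(ValueError):
            train_interaction_model(small, g, folds=5, seed=0, epochs=5)


class TestPredict:
    def test_threshold_tie_is_positive_call(self, small_featureset):
        *_, fs = small_featureset
        model = InteractionModel(_complete_graph(6), 8, seed=0)
        model.fc.W.data[...] = 0.0
        model.fc.b.data[...] = 0.0  # all probabilities exactly 0.5
        df = predict_interactions(model, fs, threshold=0.5)
        assert df["call"].all()
        assert len(df) == fs.n_samples * fs.n_pairs

    def test_prediction_columns(self, small_featureset):
        *_, fs = small_featureset
        model = InteractionModel(_complete_graph(6), 8, seed=0)
        df = predict_interactions(model, fs)
        assert list(df.columns) == ["source_cluster", "target_cluster", "ligand",
                                    "receptor", "probability", "call"]
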