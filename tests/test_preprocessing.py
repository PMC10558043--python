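"""QC, normalization, variable genes, differential expression, summaries."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ccinet import ClusterLabels, ExpressionMatrix
from ccinet.lridb import LigandReceptorPair, LRIDBTable
from ccinet.preprocessing import (
    EmptyResultError,
    normalize_log,
    ppi_project,
    qc_filter,
    read_labels,
    select_hvg,
    truncated_mean,
    wilcoxon_de,
)


class TestQCFilter:
    def test_all_zero_gene_removed(self, tiny_matrix):
        out = qc_filter(tiny_matrix, 0.01, 0.0)
        assert "g3" not in out.gene_names

    def test_dense_positive_unchanged(self):
        X = ExpressionMatrix(np.ones((3, 4)), list("abc"), list("wxyz"))
        out = qc_filter(X)
        assert out.values.shape == (3, 4)

    def test_strict_threshold_against_enumeration_oracle(self):
        # 5 genes x 100 cells with nonzero fractions 0, 1, 2, 50, 100 %
        rng = np.random.default_rng(0)
        values = np.zeros((5, 100))
        for row, k in enumerate((0, 1, 2, 50, 100)):
            cols = rng.choice(100, size=k, replace=False)
            values[row, cols] = 1.0
        X = ExpressionMatrix(values, [f"g{i}" for i in range(5)],
                             [f"c{i}" for i in range(100)])
        out = qc_filter(X, gene_frac=0.01, cell_frac=0.0)
        expected = [f"g{i}" for i, k in enumerate((0, 1, 2, 50, 100)) if k / 100 > 0.01]
        assert list(out.gene_names) == expected  # the 1%-exactly gene is dropped

    def test_idempotent_on_own_output(self, small_counts):
        X, _ = small_counts
        once = qc_filter(X)
        twice = qc_filter(once)
        assert twice.values.shape == once.values.shape
        np.testing.assert_array_equal(twice.values, once.values)

    def test_input_untouched(self, tiny_matrix):
        before = tiny_matrix.values.copy()
        qc_filter(tiny_matrix, 0.01, 0.0)
        np.testing.assert_array_equal(tiny_matrix.values, before)

    def test_empty_result_raises(self):
        X = ExpressionMatrix(np.zeros((2, 3)) + 1e-12 * 0, list("ab"), list("xyz"))
        with pytest.raises(EmptyResultError):
            qc_filter(X)


class TestNormalizeLog:
    def test_per_cell_totals_before_log(self, small_counts):
        X, _ = small_counts
        out = normalize_log(X, scale=10000.0)
        np.testing.assert_allclose(np.expm1(out.values).sum(axis=0), 10000.0, rtol=1e-9)

    def test_zero_entry_stays_zero(self, small_counts):
        X, _ = small_counts
        out = normalize_log(X)
        assert (out.values[X.values == 0] == 0).all()

    def test_two_entry_cell_hand_value(self):
        X = ExpressionMatrix(np.array([[5.0], [5.0]]), ["g1", "g2"], ["c"])
        out = normalize_log(X, scale=10000.0)
        np.testing.assert_allclose(out.values, math.log(5001.0))

    def test_zero_total_cell_names_barcode(self):
        X = ExpressionMatrix(np.array([[1.0, 0.0]]), ["g"], ["ok", "bad"])
        with pytest.raises(ValueError, match="bad"):
            normalize_log(X)

    def test_preserves_within_cell_rank_order(self, small_counts):
        X, _ = small_counts
        out = normalize_log(X)
        for c in (0, 17, 100):
            assert np.array_equal(np.argsort(X.values[:, c], kind="stable"),
                                  np.argsort(out.values[:, c], kind="stable"))


class TestSelectHVG:
    def test_varying_gene_beats_constant(self):
        X = ExpressionMatrix(np.array([[1.0, 1.0, 1.0], [0.0, 5.0, 10.0]]),
                             ["const", "vary"], list("abc"))
        assert list(select_hvg(X, 1).gene_names) == ["vary"]

    def test_identity_when_n_top_at_least_n_genes(self, tiny_matrix):
        out = select_hvg(tiny_matrix, 4)
        np.testing.assert_array_equal(out.values, tiny_matrix.values)

    def test_ranks_by_standard_deviation(self):
        rng = np.random.default_rng(1)
        rows = [np.full(40, 3.0) + rng.normal(0, sd, 40) * 0 + np.linspace(0, sd, 40)
                for sd in (0.0, 1.0, 2.0, 3.0, 4.0)]
        X = ExpressionMatrix(np.array(rows), [f"sd{i}" for i in range(5)],
                             [f"c{i}" for i in range(40)])
        out = select_hvg(X, 2)
        assert set(out.gene_names) == {"sd3", "sd4"}  # two largest spreads

    def test_original_gene_order_preserved(self, small_counts):
        X, _ = small_counts
        out = select_hvg(X, 50)
        positions = [list(X.gene_names).index(g) for g in out.gene_names]
        assert positions == sorted(positions)


class TestWilcoxonDE:
    def test_exact_p_for_separated_groups(self):
        # cluster (4,5,6) vs rest (1,2,3): the extreme split, p = 1/20
        values = np.array([[1.0, 2.0, 3.0, 4.0, 5.0, 6.0]])
        X = ExpressionMatrix(values, ["g"], [f"c{i}" for i in range(6)])
        labels = ClusterLabels(np.array([1, 1, 1, 0, 0, 0]))
        de = wilcoxon_de(X, labels, alpha=0.05)
        np.testing.assert_allclose(de.pvalue[0, 0], 1 / 20)
        assert de.overexpressed[0, 0]
        assert not de.overexpressed[1, 0]

    def test_matches_exhaustive_enumeration_small_groups(self):
        rng = np.random.default_rng(3)
        for n1, n2 in [(3, 3), (4, 3), (5, 4), (2, 5)]:
            x = rng.permutation(np.arange(1.0, n1 + n2 + 1))[:n1]
            rest = np.setdiff1d(np.arange(1.0, n1 + n2 + 1), x)
            obs_ranks = x.sum()  # values are 1..n so value == rank
            count = sum(
                1 for comb in itertools.combinations(range(1, n1 + n2 + 1), n1)
                if sum(comb) >= obs_ranks
            )
            expected = count / math.comb(n1 + n2, n1)
            values = np.concatenate([x, rest])[None, :]
            X = ExpressionMatrix(values, ["g"],
                                 [f"c{i}" for i in range(n1 + n2)])
            labels = ClusterLabels(np.array([0] * n1 + [1] * n2))
            de = wilcoxon_de(X, labels)
            np.testing.assert_allclose(de.pvalue[0, 0], expected, atol=1e-12)

    def test_identical_distribution_not_flagged(self):
        rng = np.random.default_rng(0)
        values = rng.poisson(5.0, size=(1, 200)).astype(float)
        X = ExpressionMatrix(values, ["g"], [f"c{i}" for i in range(200)])
        labels = ClusterLabels(np.repeat([0, 1], 100))
        de = wilcoxon_de(X, labels, alpha=0.01)
        assert not de.overexpressed.any()

    def test_alpha_zero_flags_nothing(self, small_counts):
        X, labels = small_counts
        de = wilcoxon_de(X, labels, alpha=0.0)
        assert not de.overexpressed.any()

    def test_tiny_cluster_reported_undefined(self):
        values = np.arange(12.0).reshape(2, 6)
        X = ExpressionMatrix(values, ["g1", "g2"], [f"c{i}" for i in range(6)])
        labels = ClusterLabels(np.array([0, 1, 1, 1, 1, 2]), 3)
        de = wilcoxon_de(X, labels)
        assert 0 in de.undefined_clusters and 2 in de.undefined_clusters
        assert np.isnan(de.pvalue[0]).all()
        assert not de.overexpressed[0].any()

    def test_markers_detected_in_planted_data(self, small_counts):
        X, labels = small_counts
        de = wilcoxon_de(normalize_log(X), labels, alpha=1e-6)
        # cluster 0's marker block is genes 0..14
        assert de.overexpressed[0, :15].all()


class TestPPIProject:
    def _de(self, flags, genes):
        k, g = flags.shape
        return type("DE", (), {
            "overexpressed": flags,
            "genes": np.asarray(genes, dtype=object),
            "clusters": np.arange(k),
            "overexpressed_genes": lambda self, c: set(
                np.asarray(genes, dtype=object)[flags[c]]),
        })()

    def test_pair_without_overexpressed_ligand_dropped(self, toy_table):
        genes = sorted(toy_table.gene_universe)
        flags = np.zeros((2, len(genes)), dtype=bool)
        flags[0] = [g.startswith(("TGFBR", "ITG", "CCR")) for g in genes]  # receptors only
        de = self._de(flags, genes)
        assert len(ppi_project(de, set(), toy_table).pairs) == 0

    def test_overexpressed_pair_with_ppi_edge_kept(self, toy_table):
        genes = sorted(toy_table.gene_universe)
        flags = np.ones((2, len(genes)), dtype=bool)
        de = self._de(flags, genes)
        edges = {("CCL19", "CCR7")}
        out = ppi_project(de, edges, toy_table)
        assert [p.name for p in out.pairs] == ["CCL19->CCR7"]

    def test_empty_ppi_skips_edge_condition(self, toy_table):
        genes = sorted(toy_table.gene_universe)
        de = self._de(np.ones((2, len(genes)), dtype=bool), genes)
        assert len(ppi_project(de, set(), toy_table).pairs) == 3


class TestTruncatedMean:
    def test_constant_vector(self):
        assert truncated_mean([7.0] * 9) == 7.0

    def test_zero_truncation_is_mean(self):
        vals = [1.0, 2.0, 9.0]
        assert truncated_mean(vals, 0.0) == pytest.approx(np.mean(vals))

    def test_ten_percent_on_1_to_10(self):
        assert truncated_mean(list(range(1, 11)), 0.10) == pytest.approx(5.5)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            truncated_mean([])

    @given(st.lists(st.floats(-1e4, 1e4), min_size=1, max_size=30),
           st.floats(0.0, 0.49))
    @settings(max_examples=100, deadline=None)
    def test_bounded_by_min_and_max(self, values, trunc):
        m = truncated_mean(values, trunc)
        assert min(values) - 1e-9 <= m <= max(values) + 1e-9

    @pytest.mark.parametrize("n", [3, 5, 7])
    def test_limits_to_median_on_odd_lengths(self, n):
        rng = np.random.default_rng(n)
        vals = rng.normal(size=n)
        m = truncated_mean(vals, 0.5 - 1e-9)
        assert m == pytest.approx(np.median(vals))


def test_read_labels_aligns_to_barcodes(tmp_path):
    p = tmp_path / "labels.csv"
    p.write_text("barcode,label\nc2,B\nc1,A\nc3,A\n")
    labels = read_labels(p, ["c1", "c2", "c3"])
    assert labels.n_clusters == 2
    assert labels.labels.tolist() == [0, 1, 0]
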