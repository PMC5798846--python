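"""Fold-enrichment vectors and the three candidate-ranking methods."""

import math

import numpy as np
import pandas as pd
import pytest

from hapscreen.quantify import derive_statistics
from hapscreen.ranking import (fisher_rank, fold_enrichment,
                               local_outlier_factor, lof_rank, rank_method)
from oracles import fisher_tail_exact, lof_bruteforce


def counts_table(genes, exonic, sense, anti):
    frame = pd.DataFrame({
        "n_exonic": exonic, "n_intron_sense": sense, "n_intron_anti": anti,
    }, index=pd.Index(genes, name="gene"))
    return derive_statistics(frame)


def di_table(genes, di):
    """Table with the requested D.I. carried entirely by exonic counts."""
    return counts_table(genes, di, [0] * len(genes), [0] * len(genes))


class TestFoldEnrichment:
    def test_pseudocounted_ratio(self):
        sel = counts_table(["g"], [8], [0], [0])
        ctl = counts_table(["g"], [4], [0], [0])
        fe = fold_enrichment(sel, ctl, 1)
        assert fe.loc["g", "fe_II"] == pytest.approx(9 / 5)

    def test_gene_absent_from_control(self):
        sel = counts_table(["g"], [9], [0], [0])
        ctl = counts_table(["g"], [0], [0], [0])
        assert fold_enrichment(sel, ctl).loc["g", "fe_II"] == pytest.approx(10.0)

    def test_identical_tables_give_unit_vectors(self):
        t = counts_table(["a", "b"], [3, 1], [2, 0], [1, 5])
        fe = fold_enrichment(t, t)
        assert np.allclose(fe.to_numpy(), 1.0)

    def test_universe_mismatch_rejected(self):
        sel = counts_table(["a"], [1], [0], [0])
        ctl = counts_table(["b"], [1], [0], [0])
        with pytest.raises(ValueError, match="mismatch"):
            fold_enrichment(sel, ctl)

    def test_vectors_positive_and_finite(self):
        sel = counts_table(["a", "b"], [0, 50], [0, 30], [0, 0])
        ctl = counts_table(["a", "b"], [0, 0], [0, 0], [0, 40])
        fe = fold_enrichment(sel, ctl)
        assert (fe.to_numpy() > 0).all()
        assert np.isfinite(fe.to_numpy()).all()


class TestLocalOutlierFactor:
    def test_matches_bruteforce_on_random_clouds(self):
        rng = np.random.default_rng(123)
        for n, k in [(30, 5), (60, 10), (90, 20)]:
            X = rng.normal(size=(n, 3))
            got = local_outlier_factor(X, k)
            expected = lof_bruteforce(X.tolist(), k)
            assert np.allclose(got, expected, atol=1e-9)

    def test_duplicate_cloud_scores_one_and_outlier_ranks_first(self):
        X = np.array([[1.0, 1.0, 1.0]] * 100 + [[20.0, 30.0, 15.0]])
        lof = local_outlier_factor(X, 20)
        assert np.allclose(lof[:100], 1.0)
        assert lof[100] == lof.max() and lof[100] > 1.0

    def test_all_identical_points_score_one(self):
        X = np.ones((25, 3))
        assert np.allclose(local_outlier_factor(X, 5), 1.0)

    def test_planted_singleton_beats_two_tight_clusters(self):
        rng = np.random.default_rng(7)
        cluster_a = rng.normal(0.0, 0.05, size=(50, 3))
        cluster_b = rng.normal(8.0, 0.05, size=(50, 3))
        outlier = np.array([[4.0, 4.0, 20.0]])
        X = np.vstack([cluster_a, cluster_b, outlier])
        lof = local_outlier_factor(X, 5)
        assert lof[100] == lof.max()
        assert np.allclose(lof, lof_bruteforce(X.tolist(), 5), atol=1e-9)

    def test_uniform_scaling_invariance(self):
        rng = np.random.default_rng(11)
        X = rng.lognormal(size=(80, 3))
        assert np.allclose(
            local_outlier_factor(X, 10), local_outlier_factor(X * 37.5, 10),
            rtol=1e-9,
        )

    def test_agrees_with_sklearn_on_tie_free_cloud(self):
        """Independent library cross-check on a continuous cloud."""
        from sklearn.neighbors import LocalOutlierFactor
        rng = np.random.default_rng(5)
        X = rng.normal(size=(120, 3))
        ours = local_outlier_factor(X, 15)
        ref = -LocalOutlierFactor(n_neighbors=15).fit(X).negative_outlier_factor_
        assert np.allclose(ours, ref, rtol=1e-8)

    def test_k_bounds_enforced(self):
        with pytest.raises(ValueError):
            local_outlier_factor(np.zeros((5, 3)), 5)


class TestLofRank:
    def test_outlier_gene_ranked_first(self):
        genes = [f"g{i:03d}" for i in range(40)]
        vectors = pd.DataFrame(
            {"fe_II": 1.0, "fe_DI": 1.0, "fe_bias": 1.0},
            index=pd.Index(genes, name="gene"),
        )
        rng = np.random.default_rng(3)
        vectors.iloc[:, :] += rng.normal(0, 0.01, size=(40, 3))
        vectors.loc["g007"] = [15.0, 25.0, 9.0]
        ranked = lof_rank(vectors, k=10)
        assert ranked.iloc[0]["gene"] == "g007"
        assert list(ranked["rank_position"]) == list(range(1, 41))

    def test_needs_more_genes_than_k(self):
        vectors = pd.DataFrame({"fe_II": [1.0] * 5, "fe_DI": 1.0, "fe_bias": 1.0},
                               index=pd.Index(list("abcde"), name="gene"))
        with pytest.raises(ValueError):
            lof_rank(vectors, k=5)


class TestFisherRank:
    def test_single_count_table_gives_half(self):
        # one D.I. in selected, one in control, on different genes:
        # the focal gene's table is [[1, 0], [0, 1]] -> one-sided p = 0.5
        sel = di_table(["a", "b"], [1, 0])
        ctl = di_table(["a", "b"], [0, 1])
        ranked = fisher_rank(sel, ctl)
        assert ranked.set_index("gene").loc["a", "score"] == pytest.approx(0.5)

    def test_zero_selected_di_gives_p_one(self):
        sel = di_table(["a", "b"], [0, 10])
        ctl = di_table(["a", "b"], [5, 5])
        ranked = fisher_rank(sel, ctl).set_index("gene")
        assert ranked.loc["a", "score"] == pytest.approx(1.0)

    def test_matches_exact_enumeration_on_random_tables(self):
        rng = np.random.default_rng(17)
        for _ in range(50):
            a, b, c, d = rng.integers(0, 15, size=4)
            if a + b == 0 or c + d == 0:
                continue
            sel = di_table(["g", "rest"], [int(a), int(b)])
            ctl = di_table(["g", "rest"], [int(c), int(d)])
            p = fisher_rank(sel, ctl).set_index("gene").loc["g", "score"]
            assert p == pytest.approx(fisher_tail_exact(int(a), int(b), int(c), int(d)),
                                      abs=1e-10)

    def test_p_values_in_unit_interval_and_monotone(self):
        """With margins fixed, more selected D.I. never increases p."""
        total_sel, total_ctl, gene_total = 40, 40, 12
        last = 1.1
        for a in range(0, gene_total + 1):
            c = gene_total - a
            sel = di_table(["g", "rest"], [a, total_sel - a])
            ctl = di_table(["g", "rest"], [c, total_ctl - c])
            p = fisher_rank(sel, ctl).set_index("gene").loc["g", "score"]
            assert 0.0 < p <= 1.0
            assert p <= last + 1e-12
            last = p

    def test_zero_total_di_rejected(self):
        sel = di_table(["a"], [0])
        ctl = di_table(["a"], [3])
        with pytest.raises(ValueError, match="zero total"):
            fisher_rank(sel, ctl)


class TestRankMethod:
    def test_hand_computed_scores(self):
        sel = di_table(["A", "B", "C"], [10, 5, 1])
        ctl = di_table(["A", "B", "C"], [1, 2, 3])
        ranked = rank_method(sel, ctl).set_index("gene")
        assert ranked.loc["A", "score"] == pytest.approx(math.log(1) - math.log(3))
        assert ranked.loc["B", "score"] == pytest.approx(0.0)
        assert ranked.loc["C", "score"] == pytest.approx(math.log(3) - math.log(1))
        assert list(rank_method(sel, ctl)["gene"]) == ["A", "B", "C"]

    def test_identical_datasets_score_zero(self):
        t = di_table(["a", "b", "c"], [4, 4, 1])  # includes a tie
        assert np.allclose(rank_method(t, t)["score"], 0.0)

    def test_swapping_pools_negates_scores(self):
        rng = np.random.default_rng(23)
        genes = [f"g{i}" for i in range(30)]
        sel = di_table(genes, rng.integers(0, 50, size=30).tolist())
        ctl = di_table(genes, rng.integers(0, 50, size=30).tolist())
        fwd = rank_method(sel, ctl).set_index("gene")["score"]
        rev = rank_method(ctl, sel).set_index("gene")["score"]
        assert np.allclose(fwd + rev.loc[fwd.index], 0.0)
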