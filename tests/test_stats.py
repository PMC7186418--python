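"""Cluster frequencies, marker ranking, Welch tests, overlay scaling."""

import numpy as np
import pandas as pd
import pytest

from ductmap import (
    CellMeta,
    ClusterAssignment,
    ExpressionMatrix,
    GenePanel,
    cluster_frequencies,
    gene_overlay_scale,
    identify_emergent_cluster,
    prepost_comparison,
    rank_markers,
    welch_test,
)
from ductmap.stats import stars_for_p


def make_assignment(labels, k, cell_ids=None):
    labels = np.asarray(labels)
    cents = np.zeros((k, 1))
    return ClusterAssignment(
        labels=labels, k=k, centroids=cents, linkage_record=np.zeros((0, 4)),
        cell_ids=cell_ids,
    )


def make_expression(et, groups, genes=None):
    et = np.asarray(et, dtype=float)
    genes = genes or tuple(f"g{i}" for i in range(et.shape[1]))
    cells = tuple(
        CellMeta(f"c{i:03d}", g) for i, g in enumerate(groups)
    )
    return ExpressionMatrix(cells=cells, panel=GenePanel(tuple(genes)), et=et)


class TestClusterFrequencies:
    def test_simple_counting(self):
        asg = make_assignment([1, 1, 2], k=2)
        meta = [CellMeta(f"c{i}", "day1") for i in range(3)]
        freq = cluster_frequencies(asg, meta)
        assert freq.fraction.tolist() == [2 / 3, 1 / 3]
        assert freq.n_cells.tolist() == [2, 1]

    def test_fractions_sum_to_one_per_group_and_counts_conserved(self):
        rng = np.random.default_rng(0)
        groups = rng.choice(["littermate_control", "day1", "day7"], size=60)
        labels = rng.integers(1, 5, size=60)
        asg = make_assignment(labels, k=4)
        meta = [CellMeta(f"c{i}", g) for i, g in enumerate(groups)]
        freq = cluster_frequencies(asg, meta)
        for g, sub in freq.groupby("group"):
            assert np.isclose(sub.fraction.sum(), 1.0)
            assert sub.n_cells.sum() == (groups == g).sum()

    def test_mismatched_lengths_rejected(self):
        asg = make_assignment([1, 2], k=2)
        with pytest.raises(ValueError):
            cluster_frequencies(asg, [CellMeta("c0", "day1")])


class TestIdentifyEmergentCluster:
    def test_picks_largest_control_to_post_gain(self):
        rows = []
        fractions = {
            ("littermate_control", 1): 0.6, ("littermate_control", 2): 0.0,
            ("littermate_control", 3): 0.4,
            ("day1", 1): 0.4, ("day1", 2): 0.3, ("day1", 3): 0.3,
            ("day3", 1): 0.5, ("day3", 2): 0.25, ("day3", 3): 0.25,
        }
        for (g, c), f in fractions.items():
            rows.append({"group": g, "cluster": c, "n_cells": int(f * 100), "fraction": f})
        assert identify_emergent_cluster(pd.DataFrame(rows)) == 2

    def test_requires_both_phases(self):
        df = pd.DataFrame(
            [{"group": "day1", "cluster": 1, "n_cells": 5, "fraction": 1.0}]
        )
        with pytest.raises(ValueError):
            identify_emergent_cluster(df)


class TestRankMarkers:
    def test_hand_built_two_cluster_example(self):
        # cluster 1: cells 0-1, cluster 2: cells 2-3
        et = make_expression(
            [[4, 0, 1], [6, 0, 1], [1, 3, 1], [1, 5, 1]],
            ["day1"] * 4,
            genes=("hi1", "hi2", "flat"),
        )
        asg = make_assignment([1, 1, 2, 2], k=2)
        table = rank_markers(et, asg, top_n=3)
        c1 = table[table.cluster == 1]
        assert c1.gene.tolist() == ["hi1", "flat", "hi2"]
        np.testing.assert_allclose(c1.log2fc.tolist(), [4.0, 0.0, -4.0])
        c2 = table[table.cluster == 2]
        assert c2.gene.tolist() == ["hi2", "flat", "hi1"]
        np.testing.assert_allclose(c2.log2fc.tolist(), [4.0, 0.0, -4.0])

    def test_identical_means_give_zero_log2fc_with_alphabetical_ties(self):
        et = make_expression(np.ones((6, 3)), ["day1"] * 6, genes=("b", "a", "c"))
        asg = make_assignment([1, 1, 1, 2, 2, 2], k=2)
        table = rank_markers(et, asg, top_n=3)
        assert (table.log2fc == 0).all()
        assert table[table.cluster == 1].gene.tolist() == ["a", "b", "c"]

    def test_default_returns_ten_rows_per_cluster(self, small_expression):
        et, _ = small_expression
        from ductmap import cluster_cells

        asg = cluster_cells(et, k=6)
        table = rank_markers(et, asg)
        assert (table.groupby("cluster").size() == 10).all()
        # within each cluster log2fc is non-increasing with rank
        for _, sub in table.groupby("cluster"):
            assert (np.diff(sub.sort_values("rank").log2fc) <= 1e-12).all()

    def test_invariant_to_cell_order(self, small_expression):
        et, _ = small_expression
        from ductmap import cluster_cells

        asg = cluster_cells(et, k=4)
        perm = np.random.default_rng(3).permutation(et.n_cells)
        et2 = ExpressionMatrix(
            cells=tuple(et.cells[i] for i in perm), panel=et.panel, et=et.et[perm]
        )
        asg2 = make_assignment(asg.labels[perm], k=4)
        a = rank_markers(et, asg, top_n=5)
        b = rank_markers(et2, asg2, top_n=5)
        pd.testing.assert_frame_equal(a, b)

    def test_empty_cluster_rejected(self):
        et = make_expression(np.ones((4, 2)), ["day1"] * 4)
        asg = make_assignment([1, 1, 1, 1], k=2)
        with pytest.raises(ValueError):
            rank_markers(et, asg, top_n=2)


def welch_oracle(a, b):
    """Independent closed-form Welch implementation (textbook formulas)."""
    from scipy.stats import t as tdist

    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    se2 = va / na + vb / nb
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2 * tdist.sf(abs(t), df)
    return t, df, p


class TestWelch:
    def test_identical_samples_are_null(self):
        r = welch_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r["t"] == 0 and r["p"] == 1 and r["stars"] == "ns"

    def test_example_matches_closed_form(self):
        a, b = np.array([1.0, 2.0, 3.0]), np.array([4.0, 5.0, 6.0, 7.0])
        r = welch_test(a, b)
        t, df, p = welch_oracle(a, b)
        assert abs(r["t"] - t) < 1e-10
        assert abs(r["df"] - df) < 1e-10
        assert abs(r["p"] - p) < 1e-10

    def test_matches_oracle_on_100_random_instances(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            na, nb = rng.integers(2, 30, size=2)
            a = rng.normal(rng.normal(), rng.uniform(0.5, 3), na)
            b = rng.normal(rng.normal(), rng.uniform(0.5, 3), nb)
            r = welch_test(a, b)
            t, df, p = welch_oracle(a, b)
            assert abs(r["t"] - t) < 1e-10
            assert abs(r["df"] - df) < 1e-10
            assert abs(r["p"] - p) < 1e-10

    def test_zero_variance_conventions(self):
        r = welch_test([2.0, 2.0, 2.0], [2.0, 2.0])
        assert r["p"] == 1.0 and r["t"] == 0.0
        r2 = welch_test([3.0, 3.0], [1.0, 1.0])
        assert r2["p"] == 0.0

    def test_small_samples_rejected(self):
        with pytest.raises(ValueError):
            welch_test([1.0], [1.0, 2.0])

    @pytest.mark.parametrize(
        "p,expected",
        [(0.2, "ns"), (0.049, "*"), (0.009, "**"), (0.0009, "***"), (0.05, "ns")],
    )
    def test_star_grading(self, p, expected):
        assert stars_for_p(p) == expected


class TestPrepostComparison:
    def _null_cohort(self, rng, n_genes=50):
        groups = (
            ["littermate_control"] * 40
            + ["surgical_control"] * 30
            + ["day1"] * 50 + ["day3"] * 50 + ["day7"] * 40
        )
        et = rng.normal(5.0, 1.0, size=(len(groups), n_genes))
        et = np.abs(et)
        return make_expression(et, groups)

    def test_type_one_error_near_nominal(self):
        """Null rejection rate at p<0.05 within 0.05 +/- 0.02 (20 seeds x 50
        genes of equal-mean pools)."""
        rejections = 0
        total = 0
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            et = self._null_cohort(rng)
            out = prepost_comparison(et)
            rejections += int((out.p < 0.05).sum())
            total += len(out)
        rate = rejections / total
        assert 0.03 <= rate <= 0.07

    def test_shifted_gene_is_detected(self):
        """A +2 log2-unit shift at study-like group sizes earns stars in
        >= 95% of seeds."""
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(2000 + seed)
            et = self._null_cohort(rng, n_genes=5)
            post = np.isin(et.groups, ["day1", "day3", "day7"])
            shifted = et.et.copy()
            shifted[post, 0] += 2.0
            et2 = ExpressionMatrix(cells=et.cells, panel=et.panel, et=shifted)
            out = prepost_comparison(et2, genes=["g0"])
            hits += int(out.stars.iloc[0] in ("*", "**", "***"))
        assert hits / 20 >= 0.95

    def test_one_row_per_requested_gene_with_bh_column(self, small_expression):
        et, _ = small_expression
        genes = list(et.panel.gene_names[:7])
        out = prepost_comparison(et, genes=genes)
        assert out.gene.tolist() == genes
        assert {"t", "df", "p", "stars", "bh_q", "log10_ctrl", "log10_pnx"} <= set(out.columns)
        assert ((out.bh_q >= out.p - 1e-12) | np.isclose(out.bh_q, out.p)).all()

    def test_surgical_controls_can_be_pooled(self, small_expression):
        et, _ = small_expression
        a = prepost_comparison(et, genes=["Vegfa"], include_surgical_controls=False)
        b = prepost_comparison(et, genes=["Vegfa"], include_surgical_controls=True)
        assert a.mean_pnx.iloc[0] == b.mean_pnx.iloc[0]
        assert a.mean_ctrl.iloc[0] != b.mean_ctrl.iloc[0]


class TestGeneOverlayScale:
    def test_simple_minmax(self):
        et = make_expression(np.array([[0.0], [2.0], [4.0]]), ["day1"] * 3)
        np.testing.assert_allclose(gene_overlay_scale(et, "g0"), [0, 0.5, 1])

    def test_constant_gene_maps_to_zero(self):
        et = make_expression(np.full((4, 1), 3.0), ["day1"] * 4)
        np.testing.assert_array_equal(gene_overlay_scale(et, "g0"), np.zeros(4))

    def test_range_is_exactly_unit_interval(self, small_expression):
        et, _ = small_expression
        v = gene_overlay_scale(et, "Vegfa")
        assert v.min() == 0.0 and v.max() == 1.0
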