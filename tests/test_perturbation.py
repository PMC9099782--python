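"""Rank transform, delta ranks, benchmark, perturbation matrix, dispersion."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.base import clone

from edgepert import (
    EdgePerturbation,
    benchmark_vector,
    delta_rank,
    dispersion_report,
    edge_perturbation,
    rank_transform,
)

from conftest import random_expression, random_network


def rank_oracle(values):
    """Independent average-rank implementation: sort-based tie averaging."""
    out = np.empty_like(values, dtype=float)
    for j in range(values.shape[1]):
        col = values[:, j]
        order = np.argsort(col, kind="stable")
        ranks = np.empty(len(col), dtype=float)
        i = 0
        while i < len(col):
            k = i
            while k + 1 < len(col) and col[order[k + 1]] == col[order[i]]:
                k += 1
            ranks[order[i : k + 1]] = (i + k) / 2.0 + 1.0
            i = k + 1
        out[:, j] = ranks
    return out


class TestRankTransform:
    def test_simple_order(self):
        expr = pd.DataFrame({"s": [3.0, 1.0, 2.0]}, index=["a", "b", "c"])
        assert rank_transform(expr)["s"].tolist() == [3.0, 1.0, 2.0]

    def test_average_ties(self):
        expr = pd.DataFrame({"s": [2.0, 2.0, 1.0]}, index=["a", "b", "c"])
        assert rank_transform(expr)["s"].tolist() == [2.5, 2.5, 1.0]

    def test_matches_oracle_with_ties(self, rng):
        values = np.round(rng.gamma(2.0, 10.0, (200, 20)), 1)  # rounding forces ties
        expr = pd.DataFrame(values, index=[f"g{i}" for i in range(200)])
        got = rank_transform(expr).to_numpy()
        np.testing.assert_array_equal(got, rank_oracle(values))

    def test_nan_rejected(self):
        expr = pd.DataFrame({"s": [1.0, np.nan]}, index=["a", "b"])
        with pytest.raises(ValueError, match="missing"):
            rank_transform(expr)

    def test_column_sum_invariant_under_ties(self, rng):
        values = np.round(rng.gamma(2.0, 3.0, (50, 5)), 0)
        ranks = rank_transform(pd.DataFrame(values, index=[f"g{i}" for i in range(50)]))
        expected = 50 * 51 / 2
        assert np.allclose(ranks.sum(axis=0), expected)


class TestDeltaRank:
    def test_subtracts_canonical_endpoint_ranks(self, small_net):
        ranks = pd.DataFrame(
            {"s": [5.0, 2.0, 4.0, 1.0]}, index=["A", "B", "C", "D"]
        )
        delta = delta_rank(ranks, small_net)
        assert delta.loc["A|B", "s"] == 3.0  # r_A - r_B
        assert delta.loc["B|C", "s"] == -2.0

    def test_missing_gene_listed(self, small_net):
        ranks = pd.DataFrame({"s": [1.0, 2.0]}, index=["A", "B"])
        with pytest.raises(ValueError, match="C"):
            delta_rank(ranks, small_net)

    def test_matches_loop_oracle(self, rng):
        net = random_network(rng, n_genes=60, n_edges=500)
        expr = random_expression(rng, net.genes, 30)
        ranks = rank_transform(expr)
        delta = delta_rank(ranks, net)
        for e_idx in rng.choice(net.n_edges, size=50, replace=False):
            a, b = net.edges[e_idx]
            expected = ranks.loc[a] - ranks.loc[b]
            np.testing.assert_array_equal(delta.iloc[e_idx].to_numpy(), expected.to_numpy())

    def test_orientation_antisymmetry(self, rng):
        net = random_network(rng, n_genes=30, n_edges=60)
        expr = random_expression(rng, net.genes, 10)
        ranks = rank_transform(expr)
        delta = delta_rank(ranks, net)
        flipped = np.empty_like(delta.to_numpy())
        for i, (a, b) in enumerate(net.edges):
            flipped[i] = (ranks.loc[b] - ranks.loc[a]).to_numpy()
        np.testing.assert_array_equal(flipped, -delta.to_numpy())


class TestBenchmarkVector:
    def test_single_normal_sample_equals_its_delta_column(self, rng):
        net = random_network(rng, n_genes=25, n_edges=50)
        expr = random_expression(rng, net.genes, 1, prefix="N")
        bench = benchmark_vector(expr, net)
        delta = delta_rank(rank_transform(expr), net)
        np.testing.assert_array_equal(bench.to_numpy(), delta.iloc[:, 0].to_numpy())

    def test_identical_normals_give_zero_perturbation(self, rng):
        net = random_network(rng, n_genes=25, n_edges=50)
        one = random_expression(rng, net.genes, 1, prefix="N")
        expr = pd.concat([one.iloc[:, [0]]] * 5, axis=1)
        expr.columns = [f"N{i}" for i in range(5)]
        bench = benchmark_vector(expr, net)
        pert = edge_perturbation(delta_rank(rank_transform(expr), net), bench)
        assert np.all(pert.to_numpy() == 0)

    def test_matches_mean_rank_subtract_oracle(self, rng):
        net = random_network(rng, n_genes=40, n_edges=150)
        expr = random_expression(rng, net.genes, 50, prefix="N")
        bench = benchmark_vector(expr, net)
        mean = expr.mean(axis=1).to_numpy()
        ref = rank_oracle(mean[:, None])[:, 0]
        pos = {g: i for i, g in enumerate(expr.index)}
        oracle = np.array([ref[pos[a]] - ref[pos[b]] for a, b in net.edges])
        np.testing.assert_array_equal(bench.to_numpy(), oracle)

    def test_zero_samples_rejected(self, rng):
        net = random_network(rng, n_genes=10, n_edges=15)
        expr = pd.DataFrame(index=list(net.genes))
        with pytest.raises(ValueError):
            benchmark_vector(expr, net)


class TestEdgePerturbation:
    def test_elementwise_subtraction(self):
        delta = pd.DataFrame({"s": [5.0]}, index=["A|B"])
        bench = pd.Series([2.0], index=["A|B"])
        assert edge_perturbation(delta, bench).loc["A|B", "s"] == 3.0

    def test_dimension_mismatch_rejected(self):
        delta = pd.DataFrame({"s": [5.0, 1.0]}, index=["A|B", "B|C"])
        bench = pd.Series([2.0], index=["A|B"])
        with pytest.raises(ValueError, match="mismatch"):
            edge_perturbation(delta, bench)

    def test_monotone_transform_invariance(self, rng):
        net = random_network(rng, n_genes=30, n_edges=80)
        expr = random_expression(rng, net.genes, 8)
        bench = benchmark_vector(expr, net)
        pert = edge_perturbation(delta_rank(rank_transform(expr), net), bench)
        warped = np.power(expr.to_numpy(), 3) * 7.0 + 1.0  # strictly increasing
        expr2 = pd.DataFrame(warped, index=expr.index, columns=expr.columns)
        pert2 = edge_perturbation(delta_rank(rank_transform(expr2), net), bench)
        np.testing.assert_array_equal(pert.to_numpy(), pert2.to_numpy())


class TestDispersionReport:
    @staticmethod
    def _setup(rng, n_edges=200, n_normal=6, n_tumor=8, tumor_scale=3.0):
        pert = np.concatenate(
            [
                rng.normal(0, 10.0, (n_edges, n_normal)),
                rng.normal(0, 10.0 * tumor_scale, (n_edges, n_tumor)),
            ],
            axis=1,
        )
        cols = [f"N{i}" for i in range(n_normal)] + [f"T{i}" for i in range(n_tumor)]
        frame = pd.DataFrame(pert, index=[f"e{i}" for i in range(n_edges)], columns=cols)
        groups = pd.Series(
            ["normal"] * n_normal + ["tumor"] * n_tumor, index=cols
        )
        return frame, groups

    def test_identical_groups_give_zero_fraction(self, rng):
        base = rng.normal(0, 5, (50, 4))
        frame = pd.DataFrame(
            np.concatenate([base, base], axis=1),
            index=[f"e{i}" for i in range(50)],
            columns=[f"N{i}" for i in range(4)] + [f"T{i}" for i in range(4)],
        )
        groups = pd.Series(["normal"] * 4 + ["tumor"] * 4, index=frame.columns)
        rep = dispersion_report(frame, groups, n_sample_edges=50, seed=0)
        assert rep.frac_edges_more_dispersed_in_tumor == 0.0
        assert rep.mean_abs_normal == pytest.approx(rep.mean_abs_tumor)

    def test_silent_normals_give_unit_fraction(self, rng):
        tumor = rng.normal(0, 5, (50, 4)) + 1.0
        frame = pd.DataFrame(
            np.concatenate([np.zeros((50, 4)), tumor], axis=1),
            index=[f"e{i}" for i in range(50)],
            columns=[f"N{i}" for i in range(4)] + [f"T{i}" for i in range(4)],
        )
        groups = pd.Series(["normal"] * 4 + ["tumor"] * 4, index=frame.columns)
        rep = dispersion_report(frame, groups, n_sample_edges=50, seed=0)
        assert rep.frac_edges_more_dispersed_in_tumor == 1.0
        assert rep.mean_abs_normal == 0.0

    def test_matches_double_loop_oracle(self, rng):
        frame, groups = self._setup(rng, n_edges=2000)
        rep = dispersion_report(frame, groups, n_sample_edges=100, seed=7)
        normal_cols = [c for c in frame.columns if c.startswith("N")]
        tumor_cols = [c for c in frame.columns if c.startswith("T")]
        tot_n = tot_t = cnt_n = cnt_t = 0
        more = 0
        for e in frame.index:
            dn = dt = 0.0
            for c in normal_cols:
                tot_n += abs(frame.loc[e, c])
                cnt_n += 1
                dn += abs(frame.loc[e, c])
            for c in tumor_cols:
                tot_t += abs(frame.loc[e, c])
                cnt_t += 1
                dt += abs(frame.loc[e, c])
            if dt / len(tumor_cols) > dn / len(normal_cols):
                more += 1
        assert rep.mean_abs_normal == pytest.approx(tot_n / cnt_n, rel=1e-12)
        assert rep.mean_abs_tumor == pytest.approx(tot_t / cnt_t, rel=1e-12)
        assert rep.frac_edges_more_dispersed_in_tumor == pytest.approx(
            more / len(frame.index), rel=1e-12
        )
        # p-value: replicate the documented sampling scheme independently
        idx = np.sort(np.random.default_rng(7).choice(2000, size=100, replace=False))
        pooled_t = np.abs(frame[tumor_cols].to_numpy()[idx]).ravel()
        pooled_n = np.abs(frame[normal_cols].to_numpy()[idx]).ravel()
        expect = stats.mannwhitneyu(pooled_t, pooled_n, alternative="two-sided").pvalue
        assert rep.sampled_edge_test_p == pytest.approx(expect, rel=1e-12)

    def test_sampled_values_are_log2_transformed(self, rng):
        frame, groups = self._setup(rng)
        rep, sampled = dispersion_report(
            frame, groups, n_sample_edges=20, seed=3, return_sampled=True
        )
        assert set(sampled["group"]) == {"normal", "tumor"}
        row = sampled.iloc[0]
        assert row["log2_abs_pert"] == pytest.approx(
            np.log2(abs(frame.loc[row["edge_id"], row["sample_id"]]) + 1.0)
        )

    def test_oversampling_rejected(self, rng):
        frame, groups = self._setup(rng, n_edges=10)
        with pytest.raises(ValueError, match="sample"):
            dispersion_report(frame, groups, n_sample_edges=11, seed=0)


class TestEdgePerturbationEstimator:
    def test_transform_matches_functional_path(self, rng):
        net = random_network(rng, n_genes=30, n_edges=80)
        normal = random_expression(rng, net.genes, 10, prefix="N")
        tumor = random_expression(rng, net.genes, 6, prefix="T")
        est = EdgePerturbation(network=net).fit(normal.T)
        got = est.transform(tumor.T)
        bench = benchmark_vector(normal, net)
        expected = edge_perturbation(delta_rank(rank_transform(tumor), net), bench)
        np.testing.assert_array_equal(got.to_numpy(), expected.T.to_numpy())
        assert list(got.columns) == list(expected.index)

    def test_sklearn_clone_roundtrip(self, small_net):
        est = EdgePerturbation(network=small_net)
        assert clone(est).get_params()["network"] == small_net

    def test_transform_before_fit_rejected(self, small_net, rng):
        est = EdgePerturbation(network=small_net)
        expr = random_expression(rng, small_net.genes, 3)
        with pytest.raises(RuntimeError):
            est.transform(expr.T)
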