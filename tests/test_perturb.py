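import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import netperturb as npb
from tests.conftest import random_instance


def brute_force_ranks(expr):
    """Independent oracle: per column, sort-based average ranks."""
    out = np.zeros(expr.shape)
    vals = expr.to_numpy()
    for j in range(vals.shape[1]):
        col = vals[:, j]
        for i, v in enumerate(col):
            less = (col < v).sum()
            equal = (col == v).sum()
            out[i, j] = less + (equal + 1) / 2.0
    return pd.DataFrame(out, index=expr.index, columns=expr.columns)


def brute_force_delta(ranks, net):
    rows = {}
    for _, (a, b, _) in net.edges.iterrows():
        rows[f"{a}|{b}"] = ranks.loc[a] - ranks.loc[b]
    return pd.DataFrame(rows).T.loc[net.edge_ids]


class TestRankTransform:
    def test_simple_column(self):
        expr = pd.DataFrame({"s": [5.0, 1.0, 3.0]}, index=["g1", "g2", "g3"])
        expr["s2"] = expr["s"]
        ranks = npb.rank_transform(expr)
        assert ranks["s"].tolist() == [3.0, 1.0, 2.0]

    def test_average_ties(self):
        expr = pd.DataFrame(
            {"s1": [2.0, 2.0, 1.0], "s2": [1.0, 2.0, 3.0]}, index=list("abc")
        )
        assert npb.rank_transform(expr)["s1"].tolist() == [2.5, 2.5, 1.0]

    def test_column_sum_conservation(self):
        rng = np.random.default_rng(3)
        expr, _ = random_instance(rng, n_genes=50, n_edges=40, n_samples=5)
        ranks = npb.rank_transform(expr)
        assert np.allclose(ranks.sum(axis=0), 50 * 51 / 2)


class TestDeltaRank:
    def test_definition(self):
        expr = pd.DataFrame({"s": [3.0, 1.0, 2.0]}, index=["g1", "g2", "g3"])
        expr["s2"] = [0.0, 1.0, 2.0]
        net = npb.network_from_edges([("g1", "g3", 1.0)], min_confidence=0.5)
        delta = npb.delta_rank(npb.rank_transform(expr), net)
        assert delta.loc["g1|g3", "s"] == 1.0

    def test_extreme_bound_attained(self):
        g = 10
        expr = pd.DataFrame(
            {"s1": np.arange(g, dtype=float), "s2": np.arange(g, dtype=float)},
            index=[f"g{i}" for i in range(g)],
        )
        net = npb.network_from_edges([("g0", "g9", 1.0)], min_confidence=0.5)
        delta = npb.delta_rank(npb.rank_transform(expr), net)
        assert abs(delta.loc["g0|g9", "s1"]) == g - 1

    def test_missing_gene_named(self, toy_expr):
        net = npb.network_from_edges([("g1", "zz", 1.0)], min_confidence=0.5)
        with pytest.raises(KeyError, match="zz"):
            npb.delta_rank(npb.rank_transform(toy_expr), net)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        expr, net = random_instance(rng, n_genes=20, n_edges=30, n_samples=10)
        ranks = npb.rank_transform(expr)
        pd.testing.assert_frame_equal(ranks, brute_force_ranks(expr))
        delta = npb.delta_rank(ranks, net)
        oracle = brute_force_delta(ranks, net)
        assert (delta.to_numpy() == oracle.to_numpy()).all()


class TestBenchmark:
    def test_single_normal_equals_own_delta(self, toy_expr):
        net = npb.network_from_edges([("g1", "g2", 1.0)], min_confidence=0.5)
        one = toy_expr[["s1"]]
        bench = npb.benchmark_from_normals(one, net)
        own = npb.delta_rank(npb.rank_transform(one), net)["s1"]
        assert (bench.to_numpy() == own.to_numpy()).all()

    def test_identical_normals_idempotent(self, toy_expr):
        net = npb.network_from_edges([("g1", "g2", 1.0)], min_confidence=0.5)
        two = pd.concat(
            [toy_expr[["s1"]], toy_expr[["s1"]].rename(columns={"s1": "s1b"})], axis=1
        )
        b1 = npb.benchmark_from_normals(toy_expr[["s1"]], net)
        b2 = npb.benchmark_from_normals(two, net)
        assert (b1.to_numpy() == b2.to_numpy()).all()

    def test_mean_then_rank_tie_case(self):
        # normals (1,2,3) and (3,2,1): mean profile is flat -> all delta 0
        expr = pd.DataFrame(
            {"n1": [1.0, 2.0, 3.0], "n2": [3.0, 2.0, 1.0]},
            index=["g1", "g2", "g3"],
        )
        net = npb.network_from_edges([("g1", "g3", 1.0)], min_confidence=0.5)
        bench = npb.benchmark_from_normals(expr, net)
        assert bench.loc["g1|g3"] == 0.0


class TestPerturbation:
    def test_self_benchmark_zero(self):
        expr = pd.DataFrame(
            {"n": [1.0, 5.0, 3.0], "t": [1.0, 5.0, 3.0]}, index=["g1", "g2", "g3"]
        )
        net = npb.network_from_edges(
            [("g1", "g2", 1.0), ("g2", "g3", 1.0)], min_confidence=0.5
        )
        bench = npb.benchmark_from_normals(expr[["n"]], net)
        delta = npb.delta_rank(npb.rank_transform(expr[["t"]]), net)
        pert = npb.perturbation(delta, bench)
        assert (pert["t"] == 0).all()
        assert npb.perturbation_magnitude(pert)["t"] == 0.0

    def test_extreme_bound(self):
        g = 6
        genes = [f"g{i}" for i in range(g)]
        up = pd.DataFrame({"t": np.arange(g, dtype=float)}, index=genes)
        down = pd.DataFrame({"n": np.arange(g, 0, -1, dtype=float)}, index=genes)
        net = npb.network_from_edges([("g0", f"g{g-1}", 1.0)], min_confidence=0.5)
        bench = npb.benchmark_from_normals(down, net)
        delta = npb.delta_rank(npb.rank_transform(up), net)
        pert = npb.perturbation(delta, bench)
        assert abs(pert.iloc[0, 0]) == 2 * (g - 1)

    def test_matches_loopwise_oracle(self):
        rng = np.random.default_rng(11)
        expr, net = random_instance(rng, n_genes=25, n_edges=40, n_samples=8)
        normals, _ = random_instance(rng, n_genes=25, n_edges=5, n_samples=6)
        normals.index = expr.index
        bench = npb.benchmark_from_normals(normals, net)
        delta = npb.delta_rank(npb.rank_transform(expr), net)
        pert = npb.perturbation(delta, bench)
        for e in net.edge_ids:
            for s in expr.columns:
                assert pert.loc[e, s] == delta.loc[e, s] - bench.loc[e]

    def test_misaligned_edges_error(self):
        delta = pd.DataFrame({"s": [1.0, 2.0]}, index=["a|b", "b|c"])
        bench = pd.Series([0.0, 1.0], index=["b|c", "a|b"])
        with pytest.raises(ValueError, match="misordered|differ"):
            npb.perturbation(delta, bench)

    def test_magnitude_arithmetic(self):
        pert = pd.DataFrame({"s": [2.0, -4.0]}, index=["a|b", "c|d"])
        assert npb.perturbation_magnitude(pert)["s"] == 3.0


class TestRankInvariance:
    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        shift=st.floats(-100, 100, allow_nan=False),
        scale=st.floats(0.1, 10, allow_nan=False),
    )
    def test_monotone_transform_leaves_statistic_unchanged(self, shift, scale):
        """Affine monotone transforms of a profile change no rank, delta or
        perturbation value."""
        rng = np.random.default_rng(5)
        expr, net = random_instance(rng, n_genes=15, n_edges=20, n_samples=4)
        normals = expr.iloc[:, :2].rename(columns=lambda c: c + "_n")
        bench = npb.benchmark_from_normals(normals, net)
        base = npb.perturbation(npb.delta_rank(npb.rank_transform(expr), net), bench)
        transformed = expr * scale + shift
        same = npb.perturbation(
            npb.delta_rank(npb.rank_transform(transformed), net), bench
        )
        assert (base.to_numpy() == same.to_numpy()).all()

    def test_column_permutation_equivariance(self):
        rng = np.random.default_rng(9)
        expr, net = random_instance(rng, n_genes=15, n_edges=20, n_samples=6)
        perm = list(expr.columns[::-1])
        d1 = npb.delta_rank(npb.rank_transform(expr), net)
        d2 = npb.delta_rank(npb.rank_transform(expr[perm]), net)
        pd.testing.assert_frame_equal(d1[perm], d2)

    def test_edge_flip_antisymmetry(self):
        rng = np.random.default_rng(13)
        expr, net = random_instance(rng, n_genes=10, n_edges=8, n_samples=3)
        ranks = npb.rank_transform(expr)
        delta = npb.delta_rank(ranks, net)
        for _, (a, b, _) in net.edges.iterrows():
            flipped = ranks.loc[b] - ranks.loc[a]
            assert (delta.loc[f"{a}|{b}"] == -flipped).all()
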