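"""ALE estimators against literal brute-force transcriptions and invariants."""

import numpy as np
import pandas as pd
import pytest

from linkale.ale import (
    ALEProfile,
    DegenerateFeatureError,
    IncompatibleProfilesError,
    aggregate_profiles,
    ale_approximate,
    ale_exact,
    ale_tabular,
    assign_bins,
    center_profile,
    make_bins,
)
from linkale.graph import AttributedGraph
from linkale.synthetic import (
    SyntheticConfig,
    generate_synthetic_graph,
    ground_truth_ale,
    true_score_function,
)

from conftest import random_graph, untrained_predictor
from oracles import brute_force_link_ale, brute_force_tabular_ale


class TestMakeBins:
    def test_single_bin_spans_support(self):
        edges = make_bins(np.array([3.0, 1.0, 2.0]), 1)
        assert np.allclose(edges, [1.0, 3.0])

    def test_uniform_edges_and_boundary_convention(self):
        edges = make_bins(np.array([1.0, 2.0, 3.0, 4.0]), 2, strategy="uniform")
        assert np.allclose(edges, [1.0, 2.5, 4.0])
        # boundary value goes to the left bin; the minimum goes to bin 0
        assert assign_bins(np.array([2.5]), edges)[0] == 0
        assert assign_bins(np.array([1.0]), edges)[0] == 0
        assert assign_bins(np.array([2.6]), edges)[0] == 1

    def test_quantile_bins_balance_counts(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(-1, 1, 1000)
        edges = make_bins(x, 5, strategy="quantile")
        counts = np.bincount(assign_bins(x, edges), minlength=5)
        assert counts.min() >= 1000 // 5 - 1 and counts.max() <= 1000 // 5 + 1

    def test_duplicate_quantiles_collapse(self):
        x = np.array([0.0] * 90 + [1.0] * 10)
        edges = make_bins(x, 5, strategy="quantile")
        assert len(edges) < 6
        assert edges[0] == 0.0 and edges[-1] == 1.0

    def test_constant_feature_rejected(self):
        with pytest.raises(DegenerateFeatureError):
            make_bins(np.ones(10), 3)


class TestTabularALE:
    def _data(self, n=60, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            {"a": rng.standard_normal(n), "x": rng.uniform(-1, 1, n)}
        )

    def test_ignored_feature_gives_flat_profile(self):
        data = self._data()
        prof = ale_tabular(lambda d: d["a"].to_numpy() * 2, data, "x", bins=5)
        assert np.allclose(prof.values, 0.0)

    def test_linear_scorer_recovered_exactly(self):
        data = self._data()
        prof = ale_tabular(lambda d: 3.0 * d["x"].to_numpy(), data, "x", bins=5)
        expected = 3.0 * (prof.bin_edges[1:] - prof.bin_edges[0])
        assert np.allclose(prof.values, expected)

    def test_quadratic_scorer_matches_brute_force(self):
        data = self._data(n=6, seed=3)
        scorer = lambda d: d["x"].to_numpy() ** 2 + d["a"].to_numpy() * d["x"].to_numpy()
        prof = ale_tabular(scorer, data, "x", bins=2)
        oracle = brute_force_tabular_ale(
            lambda row: row["x"] ** 2 + row["a"] * row["x"],
            data,
            "x",
            prof.bin_edges,
        )
        assert np.allclose(prof.values, oracle, atol=1e-10)

    def test_empty_data_rejected(self):
        with pytest.raises(ValueError):
            ale_tabular(lambda d: d["x"], pd.DataFrame(columns=["x"]), "x")


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(10))
    def test_exact_estimator_matches_literal_sum(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(8, 21))
        g = random_graph(n=n, n_features=3, p_edge=0.3, seed=seed)
        model = untrained_predictor(g, architecture="GCN" if seed % 2 else "GAT",
                                    seed=seed)
        for norm in ["global", "per_bin"]:
            prof = ale_exact(model, g, "signal", m=n, k=n - 1, bins=2,
                             seed=seed, normalization=norm)
            v_nodes, targets = prof_samples(g, n, n - 1, seed)
            oracle_vals, oracle_sums, oracle_counts = brute_force_link_ale(
                model, g, g.feature_index("signal"), prof.bin_edges,
                v_nodes, targets, normalization=norm,
            )
            assert np.allclose(prof.bin_sums, oracle_sums, atol=1e-9)
            assert np.array_equal(prof.bin_counts, oracle_counts)
            assert np.allclose(prof.values, oracle_vals, atol=1e-6)

    @pytest.mark.parametrize("seed", range(5))
    def test_approximate_matches_literal_sum_without_cross_talk(self, seed):
        # with a pairwise scorer that involves no message passing, modified
        # nodes cannot interact, so the simultaneous-modification estimator
        # must agree with the one-at-a-time transcription
        g = generate_synthetic_graph(
            SyntheticConfig(n_nodes=15, sparsity=0.5, seed=seed)
        )
        model = _TrueScoreModel(g)
        n = g.n_nodes
        prof = ale_approximate(model, g, "signal", m=n, k=n - 1, bins=2, seed=seed,
                               normalization="global")
        v_nodes, targets = prof_samples(g, n, n - 1, seed)
        oracle_vals, _, _ = brute_force_link_ale(
            model, g, g.feature_index("signal"), prof.bin_edges, v_nodes, targets,
        )
        assert np.allclose(prof.values, oracle_vals, atol=1e-6)


class _TrueScoreModel:
    """Adapter giving the generating probability the predictor interface."""

    def __init__(self, graph):
        self._f = true_score_function(graph)
        self.n_forward_passes = 0

    def predict_links(self, pairs, overrides=None):
        self.n_forward_passes += 1
        return self._f(pairs, overrides)


def prof_samples(graph, m, k, seed):
    """Replicate the estimators' subsampling (documented contract)."""
    rng = np.random.default_rng(seed)
    v = rng.choice(graph.n_nodes, size=min(m, graph.n_nodes), replace=False)
    u = rng.choice(graph.n_nodes, size=min(k, graph.n_nodes - 1), replace=False)
    return v, u


class TestExactApproximateAgreement:
    @pytest.mark.parametrize("seed", range(20))
    def test_single_modified_node_makes_variants_identical(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 16))
        g = random_graph(n=n, p_edge=0.3, seed=seed + 100)
        model = untrained_predictor(g, architecture="GAT" if seed % 3 else "GCN",
                                    seed=seed)
        kwargs = dict(feature="signal", m=1, k=min(4, n - 1),
                      bins=int(rng.integers(1, 4)), seed=seed)
        a = ale_exact(model, g, **kwargs)
        b = ale_approximate(model, g, **kwargs)
        assert np.allclose(a.values, b.values, atol=1e-6)
        assert np.array_equal(a.bin_counts, b.bin_counts)

    def test_edgeless_graph_removes_contamination(self):
        g = random_graph(n=10, p_edge=0.0, seed=4)
        model = untrained_predictor(g, seed=1)
        for m in [3, 10]:
            a = ale_exact(model, g, "signal", m=m, k=9, bins=3, seed=0)
            b = ale_approximate(model, g, "signal", m=m, k=9, bins=3, seed=0)
            assert np.allclose(a.values, b.values, atol=1e-12)

    def test_same_seed_same_samples(self, tiny_graph):
        model = untrained_predictor(tiny_graph)
        a = ale_exact(model, tiny_graph, "signal", m=5, k=5, bins=3, seed=9)
        b = ale_approximate(model, tiny_graph, "signal", m=5, k=5, bins=3, seed=9)
        assert np.array_equal(a.bin_counts, b.bin_counts)


class TestCostContract:
    def test_forward_pass_counts(self):
        g = generate_synthetic_graph(SyntheticConfig(n_nodes=80, sparsity=0.1, seed=0))
        model = untrained_predictor(g)
        H = 4
        model.n_forward_passes = 0
        ale_exact(model, g, "signal", m=20, k=10, bins=H, seed=0)
        assert model.n_forward_passes == 2 * 20
        model.n_forward_passes = 0
        ale_approximate(model, g, "signal", m=20, k=10, bins=H, seed=0)
        small_m = model.n_forward_passes
        assert small_m <= 2 * H + 1  # +1 clean pass if targets overlap the sample
        model.n_forward_passes = 0
        ale_approximate(model, g, "signal", m=60, k=10, bins=H, seed=0)
        assert model.n_forward_passes <= 2 * H + 1  # independent of m


class TestOrderInvariance:
    def test_exact_output_bitwise_stable_under_node_permutation(self, tiny_graph):
        model = untrained_predictor(tiny_graph)
        rng = np.random.default_rng(0)
        v = rng.choice(tiny_graph.n_nodes, size=8, replace=False)
        u = rng.choice(tiny_graph.n_nodes, size=6, replace=False)
        a = ale_exact(model, tiny_graph, "signal", m=8, k=6, bins=3, seed=0,
                      modified_nodes=v, target_nodes=u)
        b = ale_exact(model, tiny_graph, "signal", m=8, k=6, bins=3, seed=0,
                      modified_nodes=v[::-1], target_nodes=u)
        assert np.array_equal(a.bin_sums, b.bin_sums)
        assert np.array_equal(a.values, b.values)


class TestAggregation:
    def _random_profile(self, seed, edges=None, norm="per_bin"):
        rng = np.random.default_rng(seed)
        edges = np.array([0.0, 0.5, 1.0]) if edges is None else edges
        H = len(edges) - 1
        return ALEProfile(
            feature_name="x",
            bin_edges=edges,
            bin_sums=rng.standard_normal(H),
            bin_counts=rng.integers(1, 20, H),
            m=int(rng.integers(1, 10)),
            k=int(rng.integers(1, 10)),
            normalization=norm,
        )

    def test_single_profile_identity(self):
        p = self._random_profile(0)
        assert aggregate_profiles([p]) is p

    @pytest.mark.parametrize("seed", range(10))
    def test_partitioned_runs_aggregate_to_full_run(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(8, 16))
        g = random_graph(n=n, p_edge=0.3, seed=seed)
        model = untrained_predictor(g, seed=seed)
        v_all, u = prof_samples(g, n, n - 1, seed)
        cut = n // 2
        kw = dict(feature="signal", m=n, k=n - 1, bins=2, seed=seed,
                  target_nodes=u)
        full = ale_exact(model, g, **kw, modified_nodes=v_all)
        part1 = ale_exact(model, g, **kw, modified_nodes=v_all[:cut])
        part2 = ale_exact(model, g, **kw, modified_nodes=v_all[cut:])
        agg = aggregate_profiles([part1, part2])
        assert np.allclose(agg.bin_sums, full.bin_sums, rtol=1e-12, atol=1e-14)
        assert np.array_equal(agg.bin_counts, full.bin_counts)
        assert np.allclose(agg.values, full.values, rtol=1e-9, atol=1e-12)

    def test_associative_and_commutative_bitwise(self):
        a, b, c = (self._random_profile(s) for s in range(3))
        left = aggregate_profiles([aggregate_profiles([a, b]), c])
        flat = aggregate_profiles([a, b, c])
        assert np.array_equal(left.bin_sums, flat.bin_sums)
        assert np.array_equal(left.bin_counts, flat.bin_counts)
        swapped = aggregate_profiles([b, a, c])
        assert np.array_equal(swapped.bin_sums, flat.bin_sums)

    def test_global_mode_weighted_average_arithmetic(self):
        # two global-mode profiles with budgets 16 and 48: the aggregate is
        # the (16 g1 + 48 g2) / 64 budget-weighted average of the curves
        edges = np.array([0.0, 1.0])
        p1 = ALEProfile("x", edges, np.array([4.0]), np.array([4]), m=4, k=4,
                        normalization="global")
        p2 = ALEProfile("x", edges, np.array([24.0]), np.array([24]), m=8, k=6,
                        normalization="global")
        agg = aggregate_profiles([p1, p2])
        expected = (16 * p1.values + 48 * p2.values) / 64
        assert np.allclose(agg.values, expected)

    def test_mismatched_bins_rejected(self):
        a = self._random_profile(0)
        b = self._random_profile(1, edges=np.array([0.0, 0.4, 1.0]))
        with pytest.raises(IncompatibleProfilesError):
            aggregate_profiles([a, b])


class TestCentering:
    def test_mean_subtraction_and_idempotence(self):
        edges = np.array([0.0, 1.0, 2.0, 3.0])
        p = ALEProfile("x", edges, np.array([0.0, 0.25, 0.25]),
                       np.array([1, 1, 1]), m=3, k=1)
        assert np.allclose(p.values, [0.0, 0.25, 0.5])
        c = center_profile(p)
        assert np.allclose(c.values, [-0.25, 0.0, 0.25])
        cc = center_profile(c)
        assert np.allclose(cc.values, c.values)

    def test_constant_profile_centers_to_zero(self):
        edges = np.array([0.0, 1.0, 2.0])
        p = ALEProfile("x", edges, np.array([5.0, 0.0]), np.array([1, 1]),
                       m=2, k=1, center_offset=0.0)
        # accumulated curve is [5, 5]; centering removes the constant
        c = center_profile(p)
        assert np.allclose(c.values, 0.0)


class _SmoothedSignalPredictor:
    """Message-passing predictor with a known feature-edge response.

    Scores (v, u) as (s_v + s_u + 2)/4 where s is the signal feature
    smoothed over the graph (self-loop weight lam). Neighbor features leak
    into every node's effective signal, so modifying many nodes at once
    contaminates other nodes' predictions — a controlled stand-in for a
    feature-responsive GNN, with no training noise.
    """

    def __init__(self, graph, lam=3.0):
        from linkale.nn import gcn_adjacency

        self.graph = graph
        self.sig = graph.feature_index("signal")
        # row-normalized smoothing so the response scale stays ~1
        adj = gcn_adjacency(graph.edges, graph.n_nodes, self_loop_weight=lam)
        rows = np.asarray(adj.sum(axis=1)).ravel()
        self._adj = adj.multiply(1.0 / np.maximum(rows, 1e-12)[:, None]).tocsr()

    def predict_links(self, pairs, overrides=None):
        x = self.graph.node_features[:, self.sig].copy()
        if overrides:
            for node, val in overrides.items():
                x[node] = val[self.sig] if isinstance(val, dict) else np.asarray(val)[self.sig]
        s = self._adj @ x
        pairs = np.asarray(pairs, int).reshape(-1, 2)
        return (s[pairs[:, 0]] + s[pairs[:, 1]] + 2.0) / 4.0


class TestContaminationGrowsWithM:
    def test_approximate_diverges_from_exact_as_m_grows(self):
        # the divergence between the two estimators (not their distance to
        # the ground truth) is the quantity simultaneous modification
        # inflates: it must grow as more nodes are modified per pass
        from linkale.stats import rmse_to_reference

        g = generate_synthetic_graph(SyntheticConfig(n_nodes=600, sparsity=0.02, seed=11))
        model = _SmoothedSignalPredictor(g)
        divergence = []
        for m in [8, 64, 512]:
            ex = ale_exact(model, g, "signal", m=m, k=48, bins=5, seed=4)
            ap = ale_approximate(model, g, "signal", m=m, k=48, bins=5, seed=4)
            divergence.append(rmse_to_reference(ap, ex))
        assert divergence[0] < divergence[1] < divergence[2], divergence
        assert divergence[0] < 1e-3  # near-exact when few nodes co-modified


class TestSlopeRecovery:
    def test_true_scorer_recovers_ground_truth_slope(self):
        from linkale.stats import rmse_to_reference

        g = generate_synthetic_graph(SyntheticConfig(n_nodes=500, sparsity=0.01, seed=3))
        model = _TrueScoreModel(g)
        gt = ground_truth_ale
        for fn in [ale_exact, ale_approximate]:
            prof = fn(model, g, "signal", m=128, k=128, bins=5, seed=1)
            err = rmse_to_reference(prof, gt(prof.bin_edges))
            assert err < 0.03, fn.__name__


class TestProfileIO:
    def test_json_round_trip_preserves_doubles(self, tmp_path):
        g = random_graph(n=10, p_edge=0.3, seed=0)
        model = untrained_predictor(g)
        p = ale_exact(model, g, "signal", m=6, k=5, bins=3, seed=1)
        p.save(tmp_path / "prof.json")
        q = ALEProfile.load(tmp_path / "prof.json")
        assert np.array_equal(p.bin_sums, q.bin_sums)
        assert np.array_equal(p.bin_edges, q.bin_edges)
        assert np.array_equal(p.bin_counts, q.bin_counts)
        assert np.array_equal(p.values, q.values)
        assert q.method == "exact" and q.m == p.m and q.k == p.k
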