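"""The nine graph features against brute-force and enumeration oracles."""

import numpy as np
import pytest

from oracles import brute_metrics, enumerate_gnm, random_simple_digraph
from speechgraphs import (
    MetricConfig,
    compute_basic,
    compute_features,
    random_baseline,
    zscores,
)
from speechgraphs.graph_builder import SpeechGraph
from speechgraphs.graph_metrics import BaselineCache


def graph_from_edges(n, edges, weights=None):
    weights = weights if weights is not None else [1] * len(edges)
    g = SpeechGraph(graph_type="structural")
    g.nodes.update(f"n{i}" for i in range(n))
    for (u, v), w in zip(edges, weights):
        g.edges[(f"n{u}", f"n{v}")] = w
    return g


class TestBasicMetrics:
    def test_three_node_path(self):
        f = compute_basic(graph_from_edges(3, [(0, 1), (1, 2)]))
        assert (f.nn, f.ne, f.diameter, f.lscc) == (3, 2, 2, 1)
        assert f.aspl == pytest.approx(4 / 3)
        assert f.awd == pytest.approx(4 / 3)
        assert f.density == pytest.approx(1 / 3)

    def test_complete_three_node_digraph(self):
        edges = [(i, j) for i in range(3) for j in range(3) if i != j]
        f = compute_basic(graph_from_edges(3, edges))
        assert (f.density, f.lscc, f.diameter, f.aspl) == (1.0, 3.0, 1.0, 1.0)

    def test_empty_graph_is_all_zero_and_flagged(self):
        f = compute_basic(SpeechGraph(graph_type="structural"))
        assert all(v == 0 for v in f.as_dict().values())
        assert "empty_graph" in f.degenerate_flags

    def test_edgeless_graph_has_unit_lscc(self):
        f = compute_basic(graph_from_edges(4, []))
        assert f.lscc == 1 and f.aspl == 0 and "no_finite_path" in f.degenerate_flags

    def test_matches_brute_force_on_200_random_digraphs(self):
        rng = np.random.default_rng(123)
        for _ in range(200):
            n, edges, weights = random_simple_digraph(rng)
            expected = brute_metrics(n, edges, weights)
            got = compute_basic(graph_from_edges(n, edges, weights)).as_dict()
            for name, val in expected.items():
                assert got[name] == pytest.approx(val, abs=1e-12), (name, n, edges)

    def test_adding_an_edge_never_decreases_monotone_metrics(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            n, edges, weights = random_simple_digraph(rng, max_nodes=6)
            if n < 2:
                continue
            missing = [(i, j) for i in range(n) for j in range(n)
                       if i != j and (i, j) not in edges]
            if not missing:
                continue
            extra = missing[rng.integers(len(missing))]
            before = compute_basic(graph_from_edges(n, edges, weights))
            after = compute_basic(graph_from_edges(n, edges + [extra], weights + [1]))
            assert after.ne >= before.ne
            assert after.density >= before.density
            assert after.awd * n / 2 >= before.awd * n / 2
            assert after.lscc >= before.lscc


class TestRandomBaseline:
    def test_complete_digraph_baseline_is_degenerate(self):
        b = random_baseline(3, 6, replicates=50, seed=1)
        assert (b.sd_aspl, b.sd_lscc) == (0.0, 0.0)
        assert (b.mean_aspl, b.mean_lscc) == (1.0, 3.0)

    def test_two_node_one_edge_cases_are_isomorphic(self):
        b = random_baseline(2, 1, replicates=50, seed=1)
        assert (b.sd_aspl, b.sd_lscc) == (0.0, 0.0)
        assert (b.mean_aspl, b.mean_lscc) == (1.0, 1.0)

    def test_matches_exhaustive_enumeration_at_4_nodes_3_edges(self):
        mean_aspl, sd_aspl, mean_lscc, sd_lscc = enumerate_gnm(4, 3)
        b = random_baseline(4, 3, replicates=2000, seed=9)
        assert b.mean_lscc == pytest.approx(mean_lscc, abs=3 * sd_lscc / np.sqrt(2000))
        assert b.mean_aspl == pytest.approx(mean_aspl, abs=3 * sd_aspl / np.sqrt(2000))
        assert b.sd_aspl == pytest.approx(sd_aspl, rel=0.15)
        assert b.sd_lscc == pytest.approx(sd_lscc, rel=0.15)

    def test_out_of_range_edge_count_rejected(self):
        with pytest.raises(ValueError, match="out of range"):
            random_baseline(3, 7, replicates=10)

    def test_deterministic_given_seed(self):
        assert random_baseline(5, 8, 100, seed=3) == random_baseline(5, 8, 100, seed=3)


class TestZScores:
    def test_observed_at_mean_gives_zero(self):
        b = random_baseline(5, 8, replicates=200, seed=2)
        asplz, lsccz, _ = zscores(b.mean_aspl, b.mean_lscc, b, 5, 8)
        assert asplz == pytest.approx(0) and lsccz == pytest.approx(0)

    def test_zero_sd_baseline_flags_and_zeroes(self):
        b = random_baseline(3, 6, replicates=20, seed=2)
        asplz, lsccz, flags = zscores(1.0, 3.0, b, 3, 6)
        assert asplz == 0.0 and lsccz == 0.0
        assert {"zero_sd_aspl", "zero_sd_lscc"} <= flags

    def test_mismatched_size_rejected(self):
        b = random_baseline(3, 2, replicates=20, seed=2)
        with pytest.raises(ValueError, match="baseline is for"):
            zscores(1.0, 1.0, b, 4, 2)

    def test_isomorphism_invariance(self):
        config = MetricConfig(replicates=100, seed=4)
        g1 = graph_from_edges(4, [(0, 1), (1, 2), (2, 0)])
        g2 = SpeechGraph(graph_type="structural")
        g2.nodes.update(["x", "y", "z", "w"])
        for u, v in [("z", "x"), ("x", "y"), ("y", "z")]:
            g2.edges[(u, v)] = 1
        f1 = compute_features(g1, config)
        f2 = compute_features(g2, config)
        assert f1.as_dict() == f2.as_dict()

    def test_self_consistency_mean_z_near_zero(self):
        # graphs drawn from the same ensemble as their own baseline
        config = MetricConfig(replicates=400, seed=6)
        rng = np.random.default_rng(17)
        zs_lscc, zs_aspl = [], []
        from speechgraphs.graph_metrics import _sample_gnm_edges

        for _ in range(200):
            edges = _sample_gnm_edges(6, 10, rng)
            f = compute_features(graph_from_edges(6, [tuple(e) for e in edges]), config)
            zs_lscc.append(f.lsccz)
            zs_aspl.append(f.asplz)
        assert abs(np.mean(zs_lscc)) < 0.2
        assert abs(np.mean(zs_aspl)) < 0.2


class TestAssembly:
    def test_scene_semantic_features(self, scene_response, fast_metrics):
        from speechgraphs import build_semantic

        f = compute_features(build_semantic(scene_response.utterances), fast_metrics)
        assert (f.nn, f.ne, f.lscc) == (6, 6, 1)

    def test_repeated_call_is_deterministic(self, fast_metrics):
        g = graph_from_edges(5, [(0, 1), (1, 2), (2, 3), (3, 0)])
        f1 = compute_features(g, MetricConfig(replicates=100, seed=21))
        f2 = compute_features(g, MetricConfig(replicates=100, seed=21))
        assert f1 == f2

    def test_baselines_are_memoized(self):
        config = MetricConfig(replicates=30, seed=5)
        g = graph_from_edges(4, [(0, 1), (1, 2)])
        compute_features(g, config)
        compute_features(g, config)
        assert len(config.cache) == 1

    def test_zscore_skipping_flag(self):
        config = MetricConfig(replicates=30, seed=5, zscores=False)
        f = compute_features(graph_from_edges(3, [(0, 1)]), config)
        assert f.lsccz == 0.0 and "zscores_skipped" in f.degenerate_flags
        assert len(config.cache) == 0

    def test_cache_tsv_round_trip(self, tmp_path):
        cache = BaselineCache()
        cache.get_or_compute(5, 8, 50, 13)
        cache.save_tsv(tmp_path / "cache.tsv")
        fresh = BaselineCache()
        fresh.load_tsv(tmp_path / "cache.tsv")
        assert fresh.get_or_compute(5, 8, 50, 13) == cache.get_or_compute(5, 8, 50, 13)
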