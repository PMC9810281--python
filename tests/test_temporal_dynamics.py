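"""Temporal network construction, signed multilayer modularity, Louvain, flexibility."""

import numpy as np
import pytest

from connectoflex.network_io import RegionalTimeSeries
from connectoflex.temporal_dynamics import (
    ModularityParams,
    MultilayerPartition,
    TemporalNetwork,
    build_temporal_network,
    global_flexibility,
    louvain_multilayer,
    multilayer_modularity,
    nodal_flexibility,
    windowed_participation,
)
from conftest import clique_matrix, make_partition


def q_edge_loop(layers, g, gamma, omega):
    """Independent evaluation of the quality function, plain loops."""
    q = 0.0
    t_w = len(layers)
    n = layers[0].shape[0]
    for t, a in enumerate(layers):
        apos = np.clip(a, 0, None)
        aneg = np.clip(-a, 0, None)
        for part, sign in ((apos, 1.0), (aneg, -1.0)):
            k = part.sum(axis=1)
            two_m = k.sum()
            for i in range(n):
                for j in range(n):
                    if g[i, t] != g[j, t]:
                        continue
                    null = gamma * k[i] * k[j] / two_m if two_m > 0 else 0.0
                    q += sign * (part[i, j] - null)
    for t in range(t_w - 1):
        for i in range(n):
            if g[i, t] == g[i, t + 1]:
                q += omega
    return q


def layers_from_blocks(rng, n, t_w, labels_per_layer, signal=0.6, noise=0.1):
    layers = []
    for t in range(t_w):
        lab = labels_per_layer[:, t]
        a = np.where(lab[:, None] == lab[None, :], signal, -0.2)
        a = a + noise * rng.standard_normal((n, n))
        a = np.clip((a + a.T) / 2, -1, 1)
        np.fill_diagonal(a, 0.0)
        layers.append(a)
    return TemporalNetwork(layers=layers, node_ids=[f"r{i}" for i in range(n)])


class TestBuildTemporalNetwork:
    def test_ten_windows_of_twelve(self, rng):
        ts = RegionalTimeSeries(x=rng.standard_normal((5, 120)))
        tnet = build_temporal_network(ts, n_windows=10)
        assert tnet.n_windows == 10
        assert all(l.shape == (5, 5) for l in tnet.layers)

    def test_identical_regions_fully_correlated(self, rng):
        base = rng.standard_normal(40)
        x = np.vstack([base, base, rng.standard_normal(40)])
        tnet = build_temporal_network(RegionalTimeSeries(x=x), n_windows=4)
        for layer in tnet.layers:
            assert layer[0, 1] == pytest.approx(1.0)

    def test_too_short_window_rejected(self, rng):
        ts = RegionalTimeSeries(x=rng.standard_normal((4, 15)))
        with pytest.raises(ValueError, match="window too short"):
            build_temporal_network(ts, n_windows=10)

    def test_length_two_window_warns(self, rng):
        ts = RegionalTimeSeries(x=rng.standard_normal((4, 25)))
        with pytest.warns(UserWarning, match="degenerate"):
            tnet = build_temporal_network(ts, n_windows=10)
        assert tnet.n_windows == 10

    def test_zero_variance_region_named(self, rng):
        x = rng.standard_normal((3, 40))
        x[1, 10:20] = 7.0
        with pytest.raises(ValueError, match="region 1 .*window 2"):
            build_temporal_network(RegionalTimeSeries(x=x), n_windows=4)


class TestMultilayerModularity:
    def test_matches_edge_loop_oracle_single_layer(self):
        a = np.zeros((6, 6))
        a[:3, :3] = clique_matrix(3)
        a[3:, 3:] = clique_matrix(3)
        tnet = TemporalNetwork(layers=[a], node_ids=[str(i) for i in range(6)])
        g = np.array([[0], [0], [0], [1], [1], [1]])
        params = ModularityParams(gamma=1.0, omega=0.0, n_runs=1)
        got = multilayer_modularity(tnet, g, params)
        want = q_edge_loop([a], g, gamma=1.0, omega=0.0)
        assert got == pytest.approx(want, abs=1e-12)

    def test_matches_edge_loop_oracle_signed_multilayer(self, rng):
        n, t_w = 8, 3
        labels = rng.integers(0, 3, (n, t_w))
        tnet = layers_from_blocks(rng, n, t_w, labels)
        g = rng.integers(0, 3, (n, t_w))
        params = ModularityParams(gamma=1.3, omega=0.7, n_runs=1)
        got = multilayer_modularity(tnet, g, params)
        want = q_edge_loop(tnet.layers, g, gamma=1.3, omega=0.7)
        assert got == pytest.approx(want, abs=1e-9)

    def test_static_partition_interlayer_term(self, rng):
        n, t_w = 5, 4
        labels = np.tile(rng.integers(0, 2, (n, 1)), (1, t_w))
        tnet = layers_from_blocks(rng, n, t_w, labels)
        omega = 1.5
        q1 = multilayer_modularity(tnet, labels, ModularityParams(omega=omega))
        q0 = multilayer_modularity(tnet, labels, ModularityParams(omega=0.0))
        assert q1 - q0 == pytest.approx(omega * n * (t_w - 1), abs=1e-9)

    def test_all_negative_layer_single_community_nonpositive(self):
        a = -0.5 * clique_matrix(4)
        tnet = TemporalNetwork(layers=[a], node_ids=list("abcd"))
        g = np.zeros((4, 1), dtype=int)
        assert multilayer_modularity(tnet, g) <= 0


class TestLouvain:
    def test_attains_exhaustive_optimum_tiny_instance(self, rng):
        # N = 4, T_w = 2 planted static two-community structure
        n, t_w = 4, 2
        labels = np.tile(np.array([[0], [0], [1], [1]]), (1, t_w))
        tnet = layers_from_blocks(rng, n, t_w, labels, noise=0.05)
        params = ModularityParams(n_runs=8, seed=3)
        best, _ = louvain_multilayer(tnet, params)
        # exhaustive search over all 4^8 label matrices (labels 0..3 suffice:
        # a partition of 4 nodes never needs more than 4 labels per layer)
        from itertools import product

        best_q = -np.inf
        for combo in product(range(n), repeat=n * t_w):
            g = np.array(combo).reshape(t_w, n).T
            q = multilayer_modularity(tnet, g, params)
            best_q = max(best_q, q)
        assert best.quality == pytest.approx(best_q, abs=1e-9)

    def test_bookkeeping_matches_from_scratch(self, rng):
        n, t_w = 12, 4
        labels = rng.integers(0, 3, (n, t_w))
        tnet = layers_from_blocks(rng, n, t_w, labels)
        params = ModularityParams(n_runs=3, seed=11)
        best, runs = louvain_multilayer(tnet, params)
        for run in runs:
            assert run.quality == pytest.approx(
                multilayer_modularity(tnet, run, params), abs=1e-9
            )

    def test_same_seed_same_result(self, rng):
        tnet = layers_from_blocks(rng, 10, 3, rng.integers(0, 2, (10, 3)))
        params = ModularityParams(n_runs=4, seed=5)
        b1, _ = louvain_multilayer(tnet, params)
        b2, _ = louvain_multilayer(tnet, params)
        np.testing.assert_array_equal(b1.g, b2.g)
        assert b1.quality == b2.quality

    def test_planted_partition_recovery_rate(self, rng):
        # strongly modular 20-node, 2-layer structure
        n, t_w = 20, 2
        planted = np.tile((np.arange(n) % 2)[:, None], (1, t_w))
        hits = 0
        n_trials = 100
        for trial in range(n_trials):
            trial_rng = np.random.default_rng(1000 + trial)
            tnet = layers_from_blocks(trial_rng, n, t_w, planted, signal=0.8, noise=0.1)
            best, _ = louvain_multilayer(tnet, ModularityParams(n_runs=1, seed=trial))
            # compare up to label permutation, per layer
            ok = all(
                len(set(zip(best.g[:, t], planted[:, t]))) == 2 for t in range(t_w)
            )
            hits += ok
        assert hits >= 95


class TestFlexibility:
    def test_closed_forms(self):
        n, t_w = 2, 10
        g = np.zeros((n, t_w), dtype=int)
        g[1] = np.arange(t_w) % 2  # switches at every transition
        part = MultilayerPartition(g=g, quality=0.0)
        f = nodal_flexibility(part, node_ids=list("ab"))
        assert f.values[0] == 0.0
        assert f.values[1] == 1.0

    def test_three_of_nine_transitions(self):
        g = np.array([[0, 1, 1, 2, 2, 2, 0, 0, 0, 0]])  # changes at 3 of 9
        f = nodal_flexibility(MultilayerPartition(g=g, quality=0.0))
        assert f.values[0] == pytest.approx(1 / 3)

    def test_averaged_over_runs(self):
        g1 = np.array([[0, 0, 0, 0]])
        g2 = np.array([[0, 1, 0, 1]])
        f = nodal_flexibility(
            [MultilayerPartition(g=g1, quality=0.0), MultilayerPartition(g=g2, quality=0.0)]
        )
        assert f.values[0] == pytest.approx(0.5)

    def test_single_window_rejected(self):
        with pytest.raises(ValueError):
            nodal_flexibility(MultilayerPartition(g=np.zeros((2, 1), dtype=int), quality=0.0))

    def test_global_flexibility_is_mean(self):
        from connectoflex.graph_metrics import NodalMetricVector

        f = NodalMetricVector(metric_name="flexibility", values=[0.0, 1.0], node_ids=["a", "b"])
        assert global_flexibility(f) == pytest.approx(0.5)
        with pytest.raises(ValueError):
            global_flexibility(
                NodalMetricVector(metric_name="flexibility", values=[], node_ids=[])
            )


class TestWindowedParticipation:
    def test_delegates_to_single_layer(self, rng):
        from connectoflex.graph_metrics import participation_coefficient

        labels = rng.integers(0, 3, (8, 4))
        tnet = layers_from_blocks(rng, 8, 4, labels)
        part = make_partition(np.arange(8) % 3)
        got = windowed_participation(tnet, part, window=1)
        want = participation_coefficient(
            tnet.layer_connectome(1), part, mode="positive_only"
        )
        np.testing.assert_allclose(got.values, want.values)

    def test_all_within_module_edges_zero_pc(self):
        lab = np.array([0, 0, 1, 1])
        a = np.where(lab[:, None] == lab[None, :], 0.8, 0.0)
        np.fill_diagonal(a, 0.0)
        ids = [f"r{i}" for i in range(4)]
        tnet = TemporalNetwork(layers=[a], node_ids=ids)
        pc = windowed_participation(tnet, make_partition(lab, ids=ids), window=1)
        np.testing.assert_allclose(pc.values, 0.0, atol=1e-15)

    def test_window_range_mean(self, rng):
        labels = rng.integers(0, 3, (8, 4))
        tnet = layers_from_blocks(rng, 8, 4, labels)
        part = make_partition(np.arange(8) % 3)
        per_window = [
            windowed_participation(tnet, part, window=t).values for t in range(2, 5)
        ]
        ranged = windowed_participation(tnet, part, window=(2, 4))
        np.testing.assert_allclose(ranged.values, np.mean(per_window, axis=0))

    def test_bad_window_index(self, rng):
        tnet = layers_from_blocks(rng, 6, 3, rng.integers(0, 2, (6, 3)))
        with pytest.raises(IndexError):
            windowed_participation(tnet, make_partition(np.arange(6) % 2), window=9)
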