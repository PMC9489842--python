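import numpy as np
import pytest

from cafcd.errors import ConfigurationError, InvalidArgumentError
from cafcd.static_topology import fit_power_law
from cafcd.synthetic_data import (
    SimConfig,
    calcium_kernel,
    default_assembly_map,
    generate_scale_free_graph,
    generate_state_sequence,
    kernel_half_width_s,
    powerlaw_degree_sequence,
    simulate_fluorescence,
)


def run_lengths(labels):
    changes = np.flatnonzero(np.diff(labels) != 0)
    bounds = np.concatenate([[0], changes + 1, [len(labels)]])
    return np.diff(bounds)


class TestStateSequence:
    def test_single_state_constant(self):
        labels = generate_state_sequence(1, 500, 50.0, seed=0)
        assert np.all(labels == 1)
        assert np.count_nonzero(np.diff(labels)) == 0

    def test_invalid_arguments(self):
        with pytest.raises(InvalidArgumentError):
            generate_state_sequence(0, 100, 10.0)
        with pytest.raises(InvalidArgumentError):
            generate_state_sequence(3, 0, 10.0)
        with pytest.raises(InvalidArgumentError):
            generate_state_sequence(3, 100, 0.5)

    def test_determinism(self):
        a = generate_state_sequence(3, 1877, 200.0, seed=7)
        b = generate_state_sequence(3, 1877, 200.0, seed=7)
        np.testing.assert_array_equal(a, b)

    def test_mean_dwell_monte_carlo(self):
        # empirical mean run length within 20% of the configured mean; the
        # final (truncated) run of each sequence is excluded from the average
        lengths = []
        for seed in range(50):
            labels = generate_state_sequence(3, 1877, 200.0, seed=seed)
            lengths.extend(run_lengths(labels)[:-1])
        assert abs(np.mean(lengths) - 200.0) < 0.2 * 200.0

    def test_all_states_visited(self):
        labels = generate_state_sequence(4, 20000, 20.0, seed=3)
        assert set(np.unique(labels)) == {1, 2, 3, 4}


class TestScaleFreeGraph:
    def test_small_graph_invariants(self):
        adj = generate_scale_free_graph(3, -1.4, seed=1)
        assert adj.shape == (3, 3)
        np.testing.assert_array_equal(adj, adj.T)
        assert np.all(np.diag(adj) == 0)
        assert set(np.unique(adj)) <= {0, 1}

    def test_invalid_arguments(self):
        with pytest.raises(InvalidArgumentError):
            generate_scale_free_graph(2, -1.4)
        with pytest.raises(InvalidArgumentError):
            generate_scale_free_graph(100, 1.4)

    def test_determinism(self):
        a = generate_scale_free_graph(200, -1.4, seed=5)
        b = generate_scale_free_graph(200, -1.4, seed=5)
        np.testing.assert_array_equal(a, b)

    def test_degree_sequence_preserved(self):
        # stub matching with swap repair must keep the planted degrees
        # (up to the single +1 parity adjustment)
        planted = np.sort(powerlaw_degree_sequence(300, -1.4))
        adj = generate_scale_free_graph(300, -1.4, seed=2)
        realized = np.sort(adj.sum(axis=1))
        assert abs(int(realized.sum()) - int(planted.sum())) <= 1
        assert np.count_nonzero(realized != planted) <= 2

    def test_slope_recovery(self):
        slopes = [
            fit_power_law(generate_scale_free_graph(1000, -1.4, seed=s).sum(axis=1))
            .parameters["slope"]
            for s in range(20)
        ]
        assert abs(np.mean(slopes) - (-1.4)) < 0.15

    def test_slope_ordering(self):
        s14 = np.mean(
            [
                fit_power_law(generate_scale_free_graph(1000, -1.4, seed=s).sum(axis=1))
                .parameters["slope"]
                for s in range(5)
            ]
        )
        s20 = np.mean(
            [
                fit_power_law(generate_scale_free_graph(1000, -2.0, seed=s).sum(axis=1))
                .parameters["slope"]
                for s in range(5)
            ]
        )
        assert s20 < s14

    def test_permutation_invariant_degree_multiset(self, rng):
        adj = generate_scale_free_graph(100, -1.4, seed=9)
        perm = rng.permutation(100)
        shuffled = adj[np.ix_(perm, perm)]
        np.testing.assert_array_equal(
            np.sort(adj.sum(axis=1)), np.sort(shuffled.sum(axis=1))
        )


class TestSimulateFluorescence:
    def test_silent_network_constant(self):
        config = SimConfig(
            n_neurons=5, n_frames=200, baseline_rate_hz=0.0, coactivation_prob=0.0, noise_sd=0.0
        )
        matrix, truth = simulate_fluorescence(config)
        assert np.all(matrix.values == 0.0)
        assert all(len(t) == 0 for t in truth.spike_trains)

    def test_determinism(self):
        config = SimConfig(n_neurons=10, n_frames=300, seed=11)
        m1, t1 = simulate_fluorescence(config)
        m2, t2 = simulate_fluorescence(config)
        np.testing.assert_array_equal(m1.values, m2.values)
        np.testing.assert_array_equal(t1.state_labels, t2.state_labels)
        np.testing.assert_array_equal(t1.structural_adjacency, t2.structural_adjacency)

    def test_kernel_half_width_guard(self):
        with pytest.raises(ConfigurationError):
            simulate_fluorescence(
                SimConfig(
                    n_neurons=5,
                    n_frames=100,
                    kernel_rise_s=2.0,
                    kernel_decay_s=60.0,
                    max_half_width_s=10.0,
                )
            )
        # fast kinetics pass the same guard
        simulate_fluorescence(
            SimConfig(n_neurons=5, n_frames=100, max_half_width_s=10.0)
        )

    def test_event_rate_conservation(self):
        # total planted events within 3 SE of the configured spontaneous rate
        rate, n, frames, T = 0.05, 10, 400, 0.1506
        p = rate * T
        total = 0
        n_seeds = 30
        for seed in range(n_seeds):
            _, truth = simulate_fluorescence(
                SimConfig(
                    n_neurons=n,
                    n_frames=frames,
                    baseline_rate_hz=rate,
                    coactivation_prob=0.0,
                    noise_sd=0.0,
                    seed=seed,
                )
            )
            total += sum(len(t) for t in truth.spike_trains)
        trials = n_seeds * n * frames
        expected = trials * p
        se = np.sqrt(trials * p * (1 - p))
        assert abs(total - expected) < 3 * se

    def test_assembly_correlation_structure(self):
        n = 20
        amap = [
            [list(range(0, n // 2)), list(range(n // 2, n))],
            [list(range(0, n, 2)), list(range(1, n, 2))],
        ]
        matrix, _ = simulate_fluorescence(
            SimConfig(
                n_neurons=n,
                n_frames=1500,
                n_states=2,
                mean_dwell_frames=250,
                assembly_map=amap,
                coactivation_prob=0.4,
                baseline_rate_hz=0.0,
                noise_sd=0.02,
                seed=4,
            )
        )
        r = np.corrcoef(matrix.values)  # brute-force correlation on raw traces
        together = np.zeros((n, n), dtype=bool)
        for partition in amap:
            for assembly in partition:
                idx = np.array(assembly)
                together[np.ix_(idx, idx)] = True
        off = ~np.eye(n, dtype=bool)
        assert r[together & off].mean() > r[~together & off].mean()

    def test_bleach_trend_monotone(self):
        config = SimConfig(
            n_neurons=5,
            n_frames=400,
            baseline_rate_hz=5.0,
            coactivation_prob=0.0,
            noise_sd=0.0,
            bleach_tau_s=10.0,
            seed=2,
        )
        matrix, _ = simulate_fluorescence(config)
        half = matrix.n_frames // 2
        assert matrix.values[:, :half].mean() > matrix.values[:, half:].mean()

    def test_assembly_map_validation(self):
        with pytest.raises(InvalidArgumentError):
            SimConfig(n_neurons=6, n_frames=100, n_states=1, assembly_map=[[[0, 1, 2]]])

    def test_default_assembly_map_partitions(self):
        amap = default_assembly_map(17, 3)
        assert len(amap) == 3
        for partition in amap:
            flat = sorted(i for assembly in partition for i in assembly)
            assert flat == list(range(17))


class TestKernel:
    def test_kernel_peak_normalized(self):
        kern = calcium_kernel(0.3, 1.5, 0.1506)
        assert kern.max() == pytest.approx(1.0)
        assert kern[0] == 0.0

    def test_half_width_bracket(self):
        hw = kernel_half_width_s(0.3, 1.5)
        assert 0.0 < hw < 10.0
        assert kernel_half_width_s(0.3, 3.0) > hw  # slower decay widens it
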