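"""Unit and property tests for the AdIF network simulator."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import meaburst as mb
from meaburst.errors import InvalidConfigError, NumericFailureError
from meaburst.network import NetworkState, group_into_electrodes


class TestConnectivity:
    def test_mean_out_degree_matches_binomial_expectation(self):
        # p (n - 1) = 49.95 expected synapses per cell; 3 binomial SEs
        degrees = []
        for seed in (1, 2, 3):
            g = mb.build_connectivity(1000, 0.05, seed)
            degrees.append(g.mean_out_degree)
        n, p = 1000, 0.05
        se = math.sqrt(p * (1 - p) * (n - 1) / n) / math.sqrt(len(degrees))
        assert abs(np.mean(degrees) - p * (n - 1)) < 3 * se

    def test_zero_probability_gives_empty_graph(self):
        g = mb.build_connectivity(64, 0.0, 0)
        assert g.n_edges == 0

    def test_full_probability_gives_complete_digraph_without_self_edges(self):
        g = mb.build_connectivity(5, 1.0, 0)
        assert g.n_edges == 20
        for i in range(5):
            assert i not in g.targets(i)

    def test_deterministic_given_seed(self):
        g1 = mb.build_connectivity(200, 0.1, 42)
        g2 = mb.build_connectivity(200, 0.1, 42)
        assert np.array_equal(g1.indices, g2.indices)
        assert np.array_equal(g1.indptr, g2.indptr)

    def test_out_degree_distribution_is_binomial(self):
        g = mb.build_connectivity(1000, 0.05, 7)
        degs = g.out_degrees
        n, p = 1000, 0.05
        assert abs(degs.mean() - p * (n - 1)) < 3 * math.sqrt(p * (1 - p) * (n - 1) / n)
        # variance should be near binomial variance, loose factor-2 band
        var = p * (1 - p) * (n - 1)
        assert var / 2 < degs.var() < var * 2

    def test_invalid_probability_rejected(self):
        with pytest.raises(InvalidConfigError):
            mb.build_connectivity(10, 1.5, 0)


class TestExternalDrive:
    def test_poisson_mean_per_step(self):
        cfg = mb.NetworkConfig(n_neurons=500, seed=0)
        rng = np.random.default_rng(0)
        counts = mb.draw_external_drive(cfg, rng, n_steps=2000)
        # mean per step = 100 synapses x 20 Hz x 0.1 ms = 0.2
        assert counts.shape == (2000, 500)
        assert abs(counts.mean() - 0.2) < 3 * math.sqrt(0.2 / counts.size)

    def test_zero_rate_gives_zero_counts(self):
        cfg = mb.NetworkConfig(n_neurons=10, ext_rate=0.0)
        counts = mb.draw_external_drive(cfg, np.random.default_rng(0), 100)
        assert counts.sum() == 0

    def test_long_run_per_synapse_rate_near_20hz(self):
        # 300 s of drive for one neuron: empirical per-synapse rate ~ 20 Hz
        cfg = mb.NetworkConfig(n_neurons=1, duration=300.0)
        rng = np.random.default_rng(123)
        counts = mb.draw_external_drive(cfg, rng, n_steps=cfg.n_steps)
        rate = counts.sum() / cfg.n_ext_synapses / cfg.duration
        se = math.sqrt(20.0 / (cfg.n_ext_synapses * cfg.duration))
        assert abs(rate - 20.0) < 3 * se

    def test_negative_rate_rejected(self):
        with pytest.raises(InvalidConfigError):
            mb.NetworkConfig(ext_rate=-1.0)


class TestIntegrateStep:
    def test_leak_relaxation_matches_closed_form(self):
        p = mb.NeuronParameters(a=0.0)
        state = NetworkState(
            V=np.array([p.E_L + 10.0]), g_e=np.zeros(1), w=np.zeros(1)
        )
        t_total, dt = 40.0, 0.1  # ms
        for _ in range(int(t_total / dt)):
            state = mb.integrate_step(state, p, dt)
        expected = p.E_L + 10.0 * math.exp(-t_total * p.g_L / p.C_m)
        assert state.V[0] == pytest.approx(expected, rel=0.01)

    def test_adaptation_decay_matches_closed_form(self):
        p = mb.NeuronParameters(a=0.0)
        state = NetworkState(
            V=np.array([p.E_L]), g_e=np.zeros(1), w=np.array([p.b])
        )
        t_total, dt = 500.0, 0.1
        for _ in range(int(t_total / dt)):
            state = mb.integrate_step(state, p, dt)
            state.V[0] = p.E_L  # hold V clamped
        expected = p.b * math.exp(-t_total / p.tau_w)
        assert state.w[0] == pytest.approx(expected, rel=0.01)

    def test_clamped_conductance_reaches_mixed_reversal_fixed_point(self):
        # steady state of the membrane equation under constant g_e
        p = mb.NeuronParameters(a=0.0, b=0.0)
        g_star = 2.0  # nS
        v_expected = (p.g_L * p.E_L + g_star * p.E_e) / (p.g_L + g_star)
        state = NetworkState(V=np.array([p.E_L]), g_e=np.zeros(1), w=np.zeros(1))
        for _ in range(20000):
            state.g_e[0] = g_star  # clamp
            state = mb.integrate_step(state, p, 0.1)
        assert state.V[0] == pytest.approx(v_expected, abs=0.05)
        # independent oracle: brute-force integration at 20x finer step
        v = p.E_L
        for _ in range(400_000):
            v += 0.005 * (p.g_L * (p.E_L - v) + g_star * (p.E_e - v)) / p.C_m
        assert state.V[0] == pytest.approx(v, abs=0.05)

    def test_conductance_decays_exponentially(self):
        p = mb.NeuronParameters()
        state = NetworkState(V=np.array([p.E_L]), g_e=np.array([3.0]), w=np.zeros(1))
        out = mb.integrate_step(state, p, 0.1)
        assert out.g_e[0] == pytest.approx(3.0 * math.exp(-0.1 / p.tau_e))

    def test_nan_state_raises_with_neuron_index(self):
        p = mb.NeuronParameters()
        state = NetworkState(
            V=np.array([p.E_L, float("nan")]), g_e=np.zeros(2), w=np.zeros(2)
        )
        with pytest.raises(NumericFailureError) as err:
            mb.integrate_step(state, p, 0.1)
        assert err.value.neuron_index == 1

    @given(start=st.floats(-90, -50.001))
    @settings(max_examples=20, deadline=None)
    def test_leak_limit_monotone_convergence(self, start):
        # with inputs and adaptation off, V approaches E_L monotonically
        p = mb.NeuronParameters(a=0.0, b=0.0)
        state = NetworkState(V=np.array([start]), g_e=np.zeros(1), w=np.zeros(1))
        gap = abs(start - p.E_L)
        for _ in range(200):
            state = mb.integrate_step(state, p, 0.1)
            new_gap = abs(state.V[0] - p.E_L)
            assert new_gap <= gap + 1e-12
            gap = new_gap


class TestApplyResets:
    def _graph_one_to_three(self):
        # neuron 0 -> {1, 2, 3}; 4 isolated
        indptr = np.array([0, 3, 3, 3, 3, 3], dtype=np.int64)
        indices = np.array([1, 2, 3], dtype=np.int32)
        return mb.ConnectivityGraph(5, indptr, indices)

    def test_spiker_reset_and_targets_incremented(self):
        p = mb.NeuronParameters()
        g = self._graph_one_to_three()
        state = NetworkState(
            V=np.full(5, p.E_L), g_e=np.zeros(5), w=np.zeros(5)
        )
        state.V[0] = p.V_th + 1.0
        out, spikers = mb.apply_resets(state, p, g)
        assert list(spikers) == [0]
        assert out.V[0] == p.V_r
        assert out.w[0] == pytest.approx(p.b)
        assert np.allclose(out.g_e[1:4], p.w_e)
        assert out.g_e[4] == 0.0

    def test_no_crossing_is_identity(self, wt_params):
        g = self._graph_one_to_three()
        state = NetworkState(
            V=np.full(5, wt_params.E_L), g_e=np.zeros(5), w=np.zeros(5)
        )
        out, spikers = mb.apply_resets(state, wt_params, g)
        assert spikers.size == 0
        assert np.array_equal(out.V, state.V)

    def test_shared_target_accumulates_double_increment(self):
        # neurons 0 and 1 both project to 2
        p = mb.NeuronParameters()
        indptr = np.array([0, 1, 2, 2], dtype=np.int64)
        indices = np.array([2, 2], dtype=np.int32)
        g = mb.ConnectivityGraph(3, indptr, indices)
        state = NetworkState(V=np.full(3, p.E_L), g_e=np.zeros(3), w=np.zeros(3))
        state.V[:2] = p.V_th + 0.5
        out, spikers = mb.apply_resets(state, p, g)
        assert set(spikers) == {0, 1}
        assert out.g_e[2] == pytest.approx(2 * p.w_e)


class TestSimulate:
    def test_no_drive_no_spikes(self):
        cfg = mb.NetworkConfig(n_neurons=20, duration=1.0, ext_rate=0.0, seed=0)
        p = mb.NeuronParameters(w_e=0.0)
        raster = mb.simulate(cfg, p)
        assert raster.total_spikes == 0

    def test_bit_reproducible_given_seed(self, tiny_config, wt_params):
        r1 = mb.simulate(tiny_config, wt_params)
        r2 = mb.simulate(tiny_config, wt_params)
        assert all(
            np.array_equal(a, b) for a, b in zip(r1.spike_times, r2.spike_times)
        )

    def test_different_seed_differs(self, tiny_config, wt_params):
        from dataclasses import replace

        r1 = mb.simulate(tiny_config, wt_params)
        r2 = mb.simulate(replace(tiny_config, seed=99), wt_params)
        assert r1.counts.sum() != r2.counts.sum() or not all(
            np.array_equal(a, b) for a, b in zip(r1.spike_times, r2.spike_times)
        )

    def test_non_integer_step_count_rejected(self, wt_params):
        cfg = mb.NetworkConfig(duration=1.0, dt=0.3)
        with pytest.raises(InvalidConfigError):
            mb.simulate(cfg, wt_params)

    def test_reference_backend_agrees_statistically(self, wt_params):
        # independent plain-numpy integrator vs the production kernel
        cfg = mb.NetworkConfig(
            n_neurons=100, duration=10.0, seed=5, v_init_jitter=2.0, w_ext=0.24
        )
        fast = mb.simulate(cfg, wt_params, method="fast")
        ref = mb.simulate(cfg, wt_params, method="reference")
        rate_fast = fast.rates().mean()
        rate_ref = ref.rates().mean()
        assert rate_ref > 0 and rate_fast > 0
        # Poisson-scale sampling error on total counts, generous 5 SE band
        tol = 5 * math.sqrt(max(fast.total_spikes, ref.total_spikes)) / (
            cfg.n_neurons * cfg.duration
        )
        assert abs(rate_fast - rate_ref) < max(tol, 0.2 * max(rate_fast, rate_ref))

    def test_scaled_wt_network_shows_recurring_network_bursts(self, wt_scaled_raster):
        # recurring windows in which a large fraction of neurons spike
        r = wt_scaled_raster
        win = 0.1
        n_win = int(r.duration / win)
        part = np.zeros(n_win)
        for t in r.spike_times:
            if t.size:
                idx = np.unique(np.minimum((t / win).astype(int), n_win - 1))
                part[idx] += 1
        frac = part / r.n_sources
        # at least 5 distinct >=50%-participation events over 60 s
        mask = frac >= 0.5
        edges = np.diff(np.concatenate(([0], mask.astype(int), [0])))
        assert (edges == 1).sum() >= 5


class TestGrouping:
    def test_grouping_preserves_total_spikes_when_no_collisions(self):
        times = (np.array([0.1]), np.array([0.2]), np.array([0.3]), np.array([0.4]))
        r = mb.SpikeRaster((0, 1, 2, 3), times, 1.0)
        g = group_into_electrodes(r, 2, seed=0)
        assert g.n_sources == 2
        assert g.total_spikes == 4

    def test_grouping_rejects_more_electrodes_than_sources(self):
        r = mb.SpikeRaster((0,), (np.array([0.1]),), 1.0)
        with pytest.raises(InvalidConfigError):
            group_into_electrodes(r, 4, seed=0)
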