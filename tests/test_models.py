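"""GIF-family simulation: filters, escape-rate spiking, reductions, toy model."""

import numpy as np
import pytest
from dataclasses import replace

from agifsim.kinetics import PotassiumCurrentModel
from agifsim.models import (AGIFParamSet, FilterCoeffs, GIFParamSet,
                            IGIFParamSet, eval_filter, simulate,
                            spike_probability, theta_infinity)
from agifsim.toy import ToyLIFParams, lif_latency_closed_form, simulate_toy


class TestFilters:
    def test_lag_zero_is_weight_sum(self):
        f = FilterCoeffs(weights=(1.0, 2.0, 3.0), timescales=(10.0, 100.0, 1000.0))
        assert eval_filter(f, 0.0) == pytest.approx(6.0)

    def test_single_term_decay(self):
        f = FilterCoeffs(weights=(2.0,), timescales=(30.0,))
        assert eval_filter(f, 30.0) == pytest.approx(2.0 * np.exp(-1))

    def test_zero_weights(self):
        f = FilterCoeffs.zeros()
        assert eval_filter(f, np.array([0.0, 10.0, 1e4])).tolist() == [0, 0, 0]

    def test_negative_lag_rejected(self):
        with pytest.raises(ValueError):
            eval_filter(FilterCoeffs.zeros(), -1.0)

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            FilterCoeffs(weights=(1.0,), timescales=(10.0, 20.0))


class TestSpikeProbability:
    def test_zero_rate(self):
        assert spike_probability(0.0, 0.1) == 0.0

    def test_log2_gives_half(self):
        # lambda dt = ln 2 -> p = 0.5 (dt in ms, lambda in Hz)
        assert spike_probability(np.log(2) * 1e4, 0.1) == pytest.approx(0.5)

    def test_rate_at_stationary_threshold(self):
        # V = V_T*, no spike history: lambda = lambda_0 = 1 Hz
        m = GIFParamSet()
        lam = m.lambda_0 * np.exp((m.V_T_star - m.V_T_star) / m.DeltaV)
        assert lam == 1.0


class TestSimulate:
    def test_rest_is_fixed_point(self):
        m = GIFParamSet(DeltaV=0.1)
        res = simulate(m, np.zeros(20000), seed=0)
        assert np.allclose(res.V, m.E_l)
        assert res.spike_count == 0

    def test_agif_reduces_to_gif_bitwise(self):
        rng = np.random.default_rng(0)
        I = 30.0 + 5.0 * rng.standard_normal(50000)
        g = GIFParamSet(eta=FilterCoeffs((5.0,) * 6), gamma=FilterCoeffs((1.0,) * 6))
        a = AGIFParamSet(eta=g.eta, gamma=g.gamma,
                         k_currents=PotassiumCurrentModel(g_A_bar=0.0, g_K_bar=0.0))
        rg, ra = simulate(g, I, seed=5), simulate(a, I, seed=5)
        assert np.array_equal(rg.V, ra.V)
        assert np.array_equal(rg.spikes, ra.spikes)

    def test_deterministic_same_seed(self):
        m = AGIFParamSet()
        I = np.full(30000, 60.0)
        r1, r2 = simulate(m, I, seed=9), simulate(m, I, seed=9)
        assert np.array_equal(r1.V, r2.V) and np.array_equal(r1.spikes, r2.spikes)

    def test_refractory_separation(self):
        m = GIFParamSet(T_ref=6.5)
        res = simulate(m, np.full(200000, 120.0), seed=1)
        assert res.spike_count > 10
        assert np.diff(res.spikes).min() >= m.T_ref

    def test_escape_rate_monotone_in_voltage(self):
        # uniformly higher drive never lowers the expected spike count
        m = GIFParamSet(DeltaV=2.0)
        counts = [simulate(m, np.full(100000, amp), seed=3).spike_count
                  for amp in (20.0, 30.0, 40.0)]
        assert counts == sorted(counts)

    def test_spikes_clamped_reproduces_voltage(self):
        # clamping to a stochastic run's own spikes reproduces its V trace
        m = AGIFParamSet(eta=FilterCoeffs((20.0,) * 6), gamma=FilterCoeffs((2.0,) * 6))
        I = np.full(50000, 70.0)
        free = simulate(m, I, seed=4)
        clamped = simulate(m, I, mode="spikes_clamped", spike_times=free.spikes)
        assert np.array_equal(free.V, clamped.V)
        assert np.array_equal(free.spikes, clamped.spikes)

    def test_nonfinite_input_rejected(self):
        m = GIFParamSet()
        I = np.zeros(100)
        I[50] = np.inf
        with pytest.raises(ValueError):
            simulate(m, I, seed=0)


class TestDeterministicLimitOracle:
    def test_firing_rate_matches_closed_form_lif(self):
        # DeltaV -> 0, no adaptation: rate has the textbook LIF closed form
        m = GIFParamSet(C=67.0, g_l=0.862, E_l=-70.0, V_T_star=-45.0,
                        DeltaV=0.01, V_reset=-55.0, T_ref=6.5)
        tau = m.tau_mem
        for I0 in (25.0, 30.0, 40.0, 60.0, 90.0):
            V_inf = m.E_l + I0 / m.g_l
            rate_cf = 1000.0 / (m.T_ref + tau * np.log(
                (V_inf - m.V_reset) / (V_inf - m.V_T_star)))
            res = simulate(m, np.full(600000, I0), seed=3)
            assert res.firing_rate() == pytest.approx(rate_cf, rel=0.02)


class TestThetaInfinity:
    def test_piecewise_values_and_clamping(self):
        m = IGIFParamSet(theta_steps=(1.0, 2.0, 3.0, 4.0, 5.0),
                         bin_edges=(-80.0, -70.0, -60.0, -50.0, -40.0, -30.0))
        assert theta_infinity(-65.0, m) == 2.0
        assert theta_infinity(-200.0, m) == 1.0  # below first edge
        assert theta_infinity(0.0, m) == 5.0  # above last edge
        assert theta_infinity(-70.0, m) == 2.0  # left-closed bins

    def test_zero_steps_reduce_to_gif(self):
        I = np.full(50000, 50.0)
        g = GIFParamSet()
        i = IGIFParamSet(theta_steps=(0.0,) * 5)
        rg, ri = simulate(g, I, seed=2), simulate(i, I, seed=2)
        assert np.array_equal(rg.V, ri.V) and np.array_equal(rg.spikes, ri.spikes)

    def test_invalid_edges_rejected(self):
        with pytest.raises(ValueError):
            IGIFParamSet(bin_edges=(-50.0, -60.0, -40.0, -30.0, -20.0, -10.0))


class TestToyModel:
    def test_latency_matches_closed_form_without_IA(self):
        p = ToyLIFParams(g_A_eff=0.0)
        res = simulate_toy(p, np.full(10000, 35.0), V0=-80.0)
        assert res.latency == pytest.approx(
            lif_latency_closed_form(p, 35.0, -80.0), abs=0.005)

    def test_no_spike_when_subthreshold(self):
        p = ToyLIFParams(g_A_eff=0.0)
        res = simulate_toy(p, np.full(5000, 10.0), V0=-70.0)
        assert res.latency is None

    def test_latency_nonincreasing_in_initial_voltage(self):
        # hyperpolarization delays the first spike, with and without I_A
        V_inj = np.full(20000, 35.0)
        for g_A in (0.0, 10.0):
            p = ToyLIFParams(g_A_eff=g_A, tau_h_eff=1.2)
            lats = [simulate_toy(p, V_inj, V0=v).latency
                    for v in (-90.0, -85.0, -80.0, -75.0)]
            assert all(l is not None for l in lats)
            assert all(a >= b for a, b in zip(lats, lats[1:]))

    def test_IA_lengthens_latency(self):
        V_inj = np.full(20000, 35.0)
        l0 = simulate_toy(ToyLIFParams(g_A_eff=0.0), V_inj, V0=-80.0).latency
        lA = simulate_toy(ToyLIFParams(g_A_eff=10.0, tau_h_eff=1.2),
                          V_inj, V0=-80.0).latency
        assert lA > 2 * l0

    def test_population_desynchronization(self):
        # 600 neurons with independent background noise: I_A raises the SD
        # of first-spike latencies and lowers the latency-histogram peak
        V_inj = np.full(15000, 35.0)
        stats = {}
        for g_A in (0.0, 10.0):
            p = ToyLIFParams(g_A_eff=g_A, tau_h_eff=1.2)
            r = simulate_toy(p, V_inj, V0=-80.0, n_neurons=600, noise_sd=2.0,
                             seed=5, record_V=False)
            lat = r.first_spike_latency[np.isfinite(r.first_spike_latency)]
            hist, _ = np.histogram(lat, bins=50, range=(0.0, 15.0))
            stats[g_A] = (np.std(lat), hist.max())
        assert stats[10.0][0] > stats[0.0][0]
        assert stats[10.0][1] < stats[0.0][1]
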