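"""FFI network: connectivity, synapses, population rates, manipulations."""

import numpy as np
import pytest

from agifsim.kinetics import PotassiumCurrentModel
from agifsim.models import AGIFParamSet
from agifsim.network import (NetworkModel, SynapseParams, apply_manipulation,
                             build_population, connect_ffi, gaba_conductance,
                             population_rate, simulate_network)
from agifsim.stimuli import make_step
from agifsim.synth import ModelBank, generate_bank


class TestConnectivity:
    def test_p_zero_and_one(self):
        assert connect_ffi(10, 20, 0.0, 0).sum() == 0
        assert np.all(connect_ffi(10, 20, 1.0, 0).sum(axis=0) == 10)

    def test_expected_in_degree(self):
        means = [connect_ffi(400, 600, 0.02, s).sum(axis=0).mean()
                 for s in range(100)]
        assert np.mean(means) == pytest.approx(8.0, abs=0.5)

    def test_invalid_p(self):
        with pytest.raises(ValueError):
            connect_ffi(10, 10, 1.5, 0)


class TestBuildPopulation:
    def test_singleton_bank_copies(self, som_bank):
        bank1 = ModelBank(cell_type="SOM", models=(som_bank.models[0],))
        pop, idx = build_population(bank1, 7, seed=0)
        assert len(pop) == 7 and all(m == pop[0] for m in pop)
        assert np.all(idx == 0)

    def test_same_seed_same_indices(self, som_bank):
        _, i1 = build_population(som_bank, 50, seed=4)
        _, i2 = build_population(som_bank, 50, seed=4)
        assert np.array_equal(i1, i2)


class TestGabaConductance:
    def test_causality_with_delay(self):
        syn = SynapseParams()
        t = np.arange(0, 50, 0.1)
        g = gaba_conductance([10.0], syn, t)
        assert np.all(g[t <= 10.0 + syn.delay] == 0.0)

    def test_peak_value_and_time(self):
        # biexponential normalized to unit peak: max is exactly g_peak at
        # the closed-form peak time after the delay
        syn = SynapseParams()
        t = np.arange(0, 200, 0.01)
        g = gaba_conductance([0.0], syn, t)
        assert g.max() == pytest.approx(syn.g_peak, rel=1e-4)
        assert t[g.argmax()] == pytest.approx(syn.delay + syn.peak_time, abs=0.02)
        assert syn.peak_time == pytest.approx(4.41, abs=0.01)

    def test_linear_summation(self):
        syn = SynapseParams()
        t = np.arange(0, 300, 0.1)
        g2 = gaba_conductance([50.0, 50.0], syn, t)
        g1 = gaba_conductance([50.0], syn, t)
        assert np.allclose(g2, 2 * g1)

    def test_invalid_kinetics_rejected(self):
        with pytest.raises(ValueError):
            SynapseParams(tau_rise=30.0, tau_decay=26.0)


class TestPopulationRate:
    def test_no_spikes(self):
        t, r = population_rate([[np.array([])] * 3], duration=100.0)
        assert np.all(r == 0.0)

    def test_single_spike_per_neuron_rate(self):
        # 600 neurons each firing once within 1 s, 1 trial -> mean 1 Hz/neuron
        rng = np.random.default_rng(0)
        spikes = [[np.array([rng.uniform(0, 1000)]) for _ in range(600)]]
        t, r = population_rate(spikes, duration=1000.0, bin_width=1.0)
        assert r.mean() == pytest.approx(1.0)

    def test_spike_count_conserved_across_binnings(self):
        rng = np.random.default_rng(1)
        spikes = [[np.sort(rng.uniform(0, 1000, 17)) for _ in range(20)]
                  for _ in range(3)]
        total = sum(s.size for tr in spikes for s in tr)
        for bin_width in (0.5, 1.0, 5.0):
            t, r = population_rate(spikes, 1000.0, bin_width)
            integral = r.sum() * bin_width * 1e-3 * 20 * 3
            assert integral == pytest.approx(total)


class TestSimulateNetwork:
    def test_rest_network_silent(self, ffi_net):
        I = np.zeros(5000)
        res = simulate_network(ffi_net, I, I, noise_sd=0.0, n_trials=1, seed=0)
        assert res.som_rate.sum() == 0.0 and res.ht_rate.sum() == 0.0

    def test_reproducible_from_master_seed(self, ffi_net):
        I = make_step(0.0, 60.0, 200.0, 600.0, 0.1)
        a = simulate_network(ffi_net, I, I, n_trials=2, seed=5)
        b = simulate_network(ffi_net, I, I, n_trials=2, seed=5)
        assert np.array_equal(a.ht_rate, b.ht_rate)
        assert np.array_equal(a.som_rate, b.som_rate)

    def test_ffi_never_increases_5ht_spiking(self, ffi_net, no_ffi_net):
        I = make_step(0.0, 80.0, 200.0, 1500.0, 0.1)
        with_ffi = simulate_network(ffi_net, I, I, n_trials=3, seed=6)
        without = simulate_network(no_ffi_net, I, I, n_trials=3, seed=6)
        n_with = sum(s.size for tr in with_ffi.ht_spikes for s in tr)
        n_without = sum(s.size for tr in without.ht_spikes for s in tr)
        assert n_with <= n_without

    def test_length_mismatch_rejected(self, ffi_net):
        with pytest.raises(ValueError):
            simulate_network(ffi_net, np.zeros(100), np.zeros(200), seed=0)


class TestManipulations:
    def test_set_gA_only_touches_conductance(self, ffi_net):
        out = apply_manipulation(ffi_net, "set_gA", value=0.0)
        for before, after in zip(ffi_net.ht_models, out.ht_models):
            assert after.k_currents.g_A_bar == 0.0
            assert after.k_currents.g_K_bar == before.k_currents.g_K_bar
            assert after.C == before.C and after.eta == before.eta
        # original untouched (deep copy)
        assert all(m.k_currents.g_A_bar > 0 for m in ffi_net.ht_models)

    def test_homogenize_som_sets_medians(self, ffi_net):
        out = apply_manipulation(ffi_net, "homogenize_som")
        assert all(m == out.som_models[0] for m in out.som_models)
        med_C = np.median([m.C for m in ffi_net.som_models])
        assert out.som_models[0].C == pytest.approx(med_C)

    def test_scale_som_input(self, ffi_net):
        out = apply_manipulation(ffi_net, "scale_som_input", factor=0.7)
        assert out.som_input_scale == pytest.approx(0.7)
        assert ffi_net.som_input_scale == 1.0

    def test_swap_adaptation_copies_filter_coefficients(self, ffi_net, som_bank):
        out = apply_manipulation(ffi_net, "swap_adaptation",
                                 source_bank=som_bank, seed=0)
        som_etas = {m.eta.weights for m in som_bank}
        for m in out.ht_models:
            assert m.eta.weights in som_etas
        # non-adaptation parameters untouched
        for before, after in zip(ffi_net.ht_models, out.ht_models):
            assert after.C == before.C and after.V_T_star == before.V_T_star

    def test_unknown_manipulation(self, ffi_net):
        with pytest.raises(ValueError):
            apply_manipulation(ffi_net, "nonsense")
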