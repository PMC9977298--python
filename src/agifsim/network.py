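"""Feedforward-inhibition network model of the dorsal raphe nucleus.

A population of SOM GABA interneuron models inhibits a population of
5-HT neuron models in a feed-forward arrangement: both populations
receive the shared external drive, SOM spikes open conductance-based
GABA_A synapses on randomly connected 5-HT models (Bernoulli
connectivity, default p = 0.02 from 400 SOM onto 600 5-HT, i.e. an
expected in-degree of 8), and each neuron additionally receives
independent background OU noise.  Synapses have a fixed reversal
potential (-76.7 mV), unit-normalized biexponential kinetics
(tau_rise 1.44 ms, tau_decay 26.0 ms) scaled to a 0.3 nS peak, and a
2.0 ms propagation delay; conductances sum linearly across spikes.

Populations are bootstrapped by sampling with replacement from a model
bank.  The module also implements the standard manipulations: forcing
g_A_bar to 0 or 10 nS, swapping adaptation filter coefficients between
cell types, homogenizing the SOM population to its parameter medians,
and scaling the SOM external drive (endocannabinoid-like modulation).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.signal import lfilter

from .kinetics import PotassiumCurrentModel
from .models import AGIFParamSet, FilterCoeffs, GIFParamSet, simulate
from .stimuli import ou_noise
from .synth import ModelBank

__all__ = [
    "SynapseParams",
    "NetworkModel",
    "NetworkResult",
    "build_population",
    "connect_ffi",
    "gaba_conductance",
    "simulate_network",
    "population_rate",
    "apply_manipulation",
]


@dataclass(frozen=True)
class SynapseParams:
    """Conductance-based GABA synapse: biexponential, unit-peak normalized."""

    E_rev: float = -76.7  # mV
    g_peak: float = 0.3  # nS, literal peak of the summed waveform per spike
    tau_rise: float = 1.44  # ms
    tau_decay: float = 26.0  # ms
    delay: float = 2.0  # ms

    def __post_init__(self) -> None:
        if not (self.tau_decay > self.tau_rise > 0):
            raise ValueError("need tau_decay > tau_rise > 0")
        if self.delay < 0:
            raise ValueError("delay must be non-negative")

    @property
    def peak_time(self) -> float:
        """Time of the waveform peak after the delay, ms."""
        tr, td = self.tau_rise, self.tau_decay
        return tr * td / (td - tr) * np.log(td / tr)

    @property
    def _norm(self) -> float:
        s = self.peak_time
        return float(np.exp(-s / self.tau_decay) - np.exp(-s / self.tau_rise))


@dataclass
class NetworkModel:
    """Two bootstrapped populations + binary connectivity + synapse params."""

    som_models: List[GIFParamSet]
    ht_models: List[GIFParamSet]
    W: np.ndarray  # (n_som, n_ht) binary
    synapse: SynapseParams = field(default_factory=SynapseParams)
    som_input_scale: float = 1.0
    meta: Dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W)
        if self.W.shape != (len(self.som_models), len(self.ht_models)):
            raise ValueError("W shape must be (n_som, n_ht)")

    @classmethod
    def build(cls, som_bank: ModelBank, ht_bank: ModelBank,
              n_som: int = 400, n_ht: int = 600, p: float = 0.02,
              synapse: Optional[SynapseParams] = None,
              seed: int = 0) -> "NetworkModel":
        ss = np.random.SeedSequence(seed).generate_state(3) >> 1
        som, _ = build_population(som_bank, n_som, int(ss[0]))
        ht, _ = build_population(ht_bank, n_ht, int(ss[1]))
        W = connect_ffi(n_som, n_ht, p, int(ss[2]))
        return cls(som_models=som, ht_models=ht, W=W,
                   synapse=synapse or SynapseParams(),
                   meta={"seed": seed, "p": p})


def build_population(bank: ModelBank, n: int, seed: int
                     ) -> Tuple[List[GIFParamSet], np.ndarray]:
    """Sample ``n`` models i.i.d. with replacement; returns (models, indices)."""
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(bank), size=n)
    return [bank.models[i] for i in idx], idx


def connect_ffi(n_pre: int = 400, n_post: int = 600, p: float = 0.02,
                seed: int = 0) -> np.ndarray:
    """Bernoulli(p) binary connectivity matrix, shape (n_pre, n_post)."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be in [0, 1]")
    rng = np.random.default_rng(seed)
    return (rng.random((n_pre, n_post)) < p).astype(np.int8)


def _biexp_filter(ind: np.ndarray, syn: SynapseParams, dt: float) -> np.ndarray:
    """Summed biexponential conductance from a spike-count array (along last axis)."""
    ad = np.exp(-dt / syn.tau_decay)
    ar = np.exp(-dt / syn.tau_rise)
    ed = lfilter([1.0], [1.0, -ad], ind, axis=-1)
    er = lfilter([1.0], [1.0, -ar], ind, axis=-1)
    return syn.g_peak / syn._norm * (ed - er)


def gaba_conductance(presyn_spikes: Sequence[float], synapse: SynapseParams,
                     t_grid: np.ndarray) -> np.ndarray:
    """Conductance trace (nS) on ``t_grid`` from one presynaptic spike train.

    Per spike, after the propagation delay:
    g(s) = g_peak [exp(-s/tau_decay) - exp(-s/tau_rise)] / norm, with norm
    making the single-spike waveform peak exactly g_peak; linear summation.
    """
    t = np.asarray(t_grid, dtype=float)
    g = np.zeros_like(t)
    for t_hat in presyn_spikes:
        s = t - t_hat - synapse.delay
        m = s > 0
        g[m] += (np.exp(-s[m] / synapse.tau_decay)
                 - np.exp(-s[m] / synapse.tau_rise))
    return synapse.g_peak / synapse._norm * g


@dataclass
class NetworkResult:
    """Spikes per population (list over trials of lists over neurons of spike
    time arrays, ms) and trial-averaged population rates (Hz/neuron)."""

    som_spikes: List[List[np.ndarray]]
    ht_spikes: List[List[np.ndarray]]
    t_rate: np.ndarray
    som_rate: np.ndarray
    ht_rate: np.ndarray
    dt: float
    rate_bin: float


def population_rate(spikes: List[List[np.ndarray]], duration: float,
                    bin_width: float = 1.0, smooth: float = 0.0) -> Tuple[np.ndarray, np.ndarray]:
    """Trial-averaged population rate (Hz/neuron) from trials x neurons spikes.

    The integral of the rate over time times (n_neurons * n_trials) equals
    the total spike count.  ``smooth`` applies an optional causal boxcar
    of that width (ms).
    """
    n_trials = len(spikes)
    n_neurons = len(spikes[0]) if n_trials else 0
    edges = np.arange(0.0, duration + bin_width, bin_width)
    counts = np.zeros(edges.size - 1)
    for trial in spikes:
        for tr in trial:
            if len(tr):
                counts += np.histogram(tr, bins=edges)[0]
    rate = counts / (max(n_neurons * n_trials, 1) * bin_width * 1e-3)
    if smooth > 0:
        k = max(int(round(smooth / bin_width)), 1)
        kernel = np.ones(k)
        rate = lfilter(kernel / k, [1.0], rate)
    return edges[:-1], rate


def simulate_network(
    net: NetworkModel,
    input_som: np.ndarray,
    input_ht: np.ndarray,
    noise_sd: float = 10.0,
    noise_tau: float = 3.0,
    n_trials: int = 20,
    dt: float = 0.1,
    seed: int = 0,
    rate_bin: float = 1.0,
) -> NetworkResult:
    """Simulate the FFI network for ``n_trials`` independent trials.

    Per trial, every neuron gets fresh independent background OU noise
    (zero mean — the stimulus carries the mean drive) added to the shared
    input; SOM neurons are simulated first and their spikes drive the
    GABA conductances of connected 5-HT neurons.  The SOM external drive
    is scaled by ``net.som_input_scale``.
    """
    input_som = np.asarray(input_som, dtype=float)
    input_ht = np.asarray(input_ht, dtype=float)
    if input_som.shape != input_ht.shape:
        raise ValueError("SOM and 5-HT inputs must have the same length")
    n_steps = input_som.size
    duration = n_steps * dt
    n_som, n_ht = len(net.som_models), len(net.ht_models)
    syn = net.synapse
    n_delay = int(round(syn.delay / dt))

    ss = np.random.SeedSequence(seed)
    trial_seeds = ss.generate_state(n_trials * (n_som + n_ht)) >> 1
    trial_seeds = trial_seeds.reshape(n_trials, n_som + n_ht)

    som_all: List[List[np.ndarray]] = []
    ht_all: List[List[np.ndarray]] = []
    W = net.W.astype(float)
    for trial in range(n_trials):
        seeds = trial_seeds[trial]
        som_spikes: List[np.ndarray] = []
        counts = np.zeros((n_som, n_steps))
        for i, m in enumerate(net.som_models):
            s = int(seeds[i])
            I = net.som_input_scale * input_som
            if noise_sd > 0:
                I = I + ou_noise(0.0, noise_sd, noise_tau, duration, dt, s + 1)
            res = simulate(m, I, dt=dt, seed=s)
            som_spikes.append(res.spikes)
            bins = np.asarray(np.rint(res.spikes / dt), dtype=int) + n_delay
            bins = bins[bins < n_steps]
            np.add.at(counts[i], bins, 1.0)
        som_all.append(som_spikes)

        if W.any():
            g_som = _biexp_filter(counts, syn, dt)  # (n_som, n_steps)
            g_post = W.T @ g_som  # (n_ht, n_steps)
        else:
            g_post = None

        ht_spikes: List[np.ndarray] = []
        for j, m in enumerate(net.ht_models):
            s = int(seeds[n_som + j])
            I = input_ht
            if noise_sd > 0:
                I = I + ou_noise(0.0, noise_sd, noise_tau, duration, dt, s + 1)
            g = g_post[j] if g_post is not None else None
            res = simulate(m, I, dt=dt, seed=s, g_syn=g, E_syn_rev=syn.E_rev)
            ht_spikes.append(res.spikes)
        ht_all.append(ht_spikes)

    t_rate, som_rate = population_rate(som_all, duration, rate_bin)
    _, ht_rate = population_rate(ht_all, duration, rate_bin)
    return NetworkResult(som_spikes=som_all, ht_spikes=ht_all, t_rate=t_rate,
                         som_rate=som_rate, ht_rate=ht_rate, dt=dt,
                         rate_bin=rate_bin)


def _median_model(models: Sequence[GIFParamSet]) -> GIFParamSet:
    """Parameter-wise median of a homogeneous list of models."""
    proto = models[0]
    med = lambda vals: float(np.median(vals))
    fields = dict(
        C=med([m.C for m in models]),
        g_l=med([m.g_l for m in models]),
        E_l=med([m.E_l for m in models]),
        eta=FilterCoeffs(
            weights=tuple(np.median([m.eta.weights for m in models], axis=0)),
            timescales=proto.eta.timescales),
        gamma=FilterCoeffs(
            weights=tuple(np.median([m.gamma.weights for m in models], axis=0)),
            timescales=proto.gamma.timescales),
        V_T_star=med([m.V_T_star for m in models]),
        DeltaV=med([m.DeltaV for m in models]),
        V_reset=med([m.V_reset for m in models]),
        T_ref=med([m.T_ref for m in models]),
    )
    if isinstance(proto, AGIFParamSet):
        kc = replace(proto.k_currents,
                     g_A_bar=med([m.k_currents.g_A_bar for m in models]),
                     g_K_bar=med([m.k_currents.g_K_bar for m in models]))
        return AGIFParamSet(k_currents=kc, **fields)
    return GIFParamSet(**fields)


def apply_manipulation(net: NetworkModel, which: str, *,
                       value: Optional[float] = None,
                       source_bank: Optional[ModelBank] = None,
                       factor: float = 0.7,
                       seed: int = 0) -> NetworkModel:
    """Return a modified deep copy of the network.

    which:
      - ``set_gA``: force g_A_bar of every 5-HT model to ``value`` (nS).
      - ``swap_adaptation``: per 5-HT model, draw one random model from
        ``source_bank`` (opposite cell type) and copy its eta and gamma
        coefficients only.
      - ``homogenize_som``: set all SOM model parameters to their
        population-wise median values.
      - ``scale_som_input``: multiply the SOM external drive by
        ``factor`` (5-HT drive untouched).
    """
    out = copy.deepcopy(net)
    if which == "set_gA":
        if value is None:
            raise ValueError("set_gA requires value=")
        new = []
        for m in out.ht_models:
            if not isinstance(m, AGIFParamSet):
                raise TypeError("set_gA requires aGIF 5-HT models")
            new.append(replace(m, k_currents=replace(m.k_currents, g_A_bar=float(value))))
        out.ht_models = new
    elif which == "swap_adaptation":
        if source_bank is None:
            raise ValueError("swap_adaptation requires source_bank=")
        rng = np.random.default_rng(seed)
        new = []
        for m in out.ht_models:
            src = source_bank.models[rng.integers(0, len(source_bank))]
            new.append(replace(
                m,
                eta=FilterCoeffs(weights=src.eta.weights, timescales=m.eta.timescales),
                gamma=FilterCoeffs(weights=src.gamma.weights, timescales=m.gamma.timescales)))
        out.ht_models = new
    elif which == "homogenize_som":
        median = _median_model(out.som_models)
        out.som_models = [median for _ in out.som_models]
    elif which == "scale_som_input":
        out.som_input_scale = out.som_input_scale * factor
    else:
        raise ValueError(f"unknown manipulation {which!r}")
    return out
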