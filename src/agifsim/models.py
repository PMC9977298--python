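"""GIF-family single-neuron models and their forward simulation.

The generalized integrate-and-fire (GIF) model combines a leaky
subthreshold integrator with two spike-triggered adaptation processes
and a stochastic (escape-rate) spiking rule:

    C dV/dt = -g_l (V - E_l) - sum_{t_hat < t} eta(t - t_hat) + I_inj(t)
    lambda(t) = lambda_0 exp[(V - V_T* - sum gamma(t - t_hat)) / DeltaV]

where eta (pA, positive = hyperpolarizing) and gamma (mV) are sums of
exponentials with fixed timescales and fitted weights, and spikes are
emitted as an inhomogeneous Poisson process with intensity lambda.

The augmented GIF (aGIF) adds the experimentally constrained potassium
currents I_A and I_K of 5-HT neurons to the subthreshold equation; the
iGIF instead adds a threshold variable theta whose equilibrium is a
piecewise-constant function of voltage (capturing e.g. sodium-channel
inactivation).  Setting g_A_bar = g_K_bar = 0 reduces the aGIF exactly to
the GIF, and theta == 0 reduces the iGIF to the GIF.

Integration is forward Euler at dt = 0.1 ms by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Tuple

import numpy as np

from ._core import integrate_gif
from .kinetics import PotassiumCurrentModel, equilibrium_gate

__all__ = [
    "FilterCoeffs",
    "GIFParamSet",
    "AGIFParamSet",
    "IGIFParamSet",
    "SimResult",
    "DEFAULT_FILTER_TIMESCALES",
    "eval_filter",
    "spike_probability",
    "theta_infinity",
    "simulate",
]

#: Fixed exponential-basis timescales (ms) for eta and gamma; log-spaced to
#: span the multi-second adaptation of 5-HT neurons.
DEFAULT_FILTER_TIMESCALES = (10.0, 30.0, 100.0, 300.0, 1000.0, 3000.0)


@dataclass(frozen=True)
class FilterCoeffs:
    """Sum-of-exponentials filter: f(t) = sum_j weights[j] exp(-t/timescales[j])."""

    weights: Tuple[float, ...] = (0.0,) * 6
    timescales: Tuple[float, ...] = DEFAULT_FILTER_TIMESCALES

    def __post_init__(self) -> None:
        if len(self.weights) != len(self.timescales):
            raise ValueError("weights and timescales must have equal length")
        ts = np.asarray(self.timescales, dtype=float)
        if not (np.all(ts > 0) and np.all(np.diff(ts) > 0)):
            raise ValueError("timescales must be strictly positive and increasing")

    @classmethod
    def zeros(cls, timescales: Sequence[float] = DEFAULT_FILTER_TIMESCALES) -> "FilterCoeffs":
        return cls(weights=(0.0,) * len(tuple(timescales)), timescales=tuple(timescales))

    def integral(self) -> float:
        """Time integral sum_j w_j tau_j (filter units * ms)."""
        return float(np.dot(self.weights, self.timescales))

    def scaled(self, factor: float) -> "FilterCoeffs":
        return FilterCoeffs(tuple(w * factor for w in self.weights), self.timescales)


def eval_filter(f: FilterCoeffs, lag):
    """Evaluate the filter at non-negative lag(s), ms."""
    lag = np.asarray(lag, dtype=float)
    if np.any(lag < 0):
        raise ValueError("lag must be non-negative")
    w = np.asarray(f.weights)
    tau = np.asarray(f.timescales)
    out = np.sum(w * np.exp(-lag[..., None] / tau), axis=-1)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class GIFParamSet:
    """Parameters of the canonical GIF model (units: mV, ms, pA, nS, pF)."""

    C: float = 67.0
    g_l: float = 0.862
    E_l: float = -70.0
    eta: FilterCoeffs = field(default_factory=FilterCoeffs.zeros)
    gamma: FilterCoeffs = field(default_factory=FilterCoeffs.zeros)
    V_T_star: float = -45.0
    DeltaV: float = 2.0
    lambda_0: float = 1.0  # Hz; fixed scale of the escape rate
    V_reset: float = -55.0
    T_ref: float = 6.5

    def __post_init__(self) -> None:
        if min(self.C, self.g_l, self.DeltaV, self.T_ref) <= 0:
            raise ValueError("C, g_l, DeltaV and T_ref must be positive")

    @property
    def tau_mem(self) -> float:
        """Membrane time constant C/g_l, ms."""
        return self.C / self.g_l


@dataclass(frozen=True)
class AGIFParamSet(GIFParamSet):
    """GIF augmented with the I_A/I_K potassium-current model."""

    k_currents: PotassiumCurrentModel = field(default_factory=PotassiumCurrentModel)


@dataclass(frozen=True)
class IGIFParamSet(GIFParamSet):
    """GIF with a voltage-coupled threshold variable theta.

    theta relaxes toward theta_inf(V) with time constant tau_theta, where
    theta_inf is piecewise constant: theta_steps[j] over
    [bin_edges[j], bin_edges[j+1]), clamped outside the edge range.
    """

    theta_steps: Tuple[float, ...] = (0.0,) * 5
    bin_edges: Tuple[float, ...] = (-100.0, -70.0, -60.0, -50.0, -40.0, 0.0)
    tau_theta: float = 5.0

    def __post_init__(self) -> None:
        super().__post_init__()
        edges = np.asarray(self.bin_edges, dtype=float)
        if len(self.bin_edges) != len(self.theta_steps) + 1:
            raise ValueError("need len(bin_edges) == len(theta_steps) + 1")
        if not np.all(np.diff(edges) > 0):
            raise ValueError("bin_edges must be strictly increasing")
        if self.tau_theta <= 0:
            raise ValueError("tau_theta must be positive")


@dataclass(frozen=True)
class SimResult:
    """Simulation output: traces at the integration dt plus spike times (ms)."""

    V: np.ndarray
    spikes: np.ndarray  # ms
    h: np.ndarray
    eta_sum: np.ndarray
    gamma_sum: np.ndarray
    theta: np.ndarray
    dt: float

    @property
    def spike_count(self) -> int:
        return int(self.spikes.size)

    def firing_rate(self) -> float:
        """Mean rate over the whole trace, Hz."""
        return self.spike_count / (self.V.size * self.dt * 1e-3)


def spike_probability(lambda_t, dt: float):
    """Per-bin spike probability 1 - exp(-lambda dt) for lambda in Hz, dt in ms."""
    lam = np.asarray(lambda_t, dtype=float)
    if np.any(lam < 0):
        raise ValueError("lambda must be non-negative")
    out = 1.0 - np.exp(-lam * dt * 1e-3)
    return out if out.ndim else float(out)


def theta_infinity(V, model: IGIFParamSet):
    """Equilibrium threshold offset theta_inf(V), mV (piecewise constant)."""
    edges = np.asarray(model.bin_edges, dtype=float)
    steps = np.asarray(model.theta_steps, dtype=float)
    idx = np.clip(np.searchsorted(edges, np.asarray(V, dtype=float), side="right") - 1,
                  0, steps.size - 1)
    out = steps[idx]
    return out if out.ndim else float(out)


def _kernel_args(model: GIFParamSet):
    """Flatten a parameter set into the kernel's scalar/array arguments."""
    use_k = isinstance(model, AGIFParamSet)
    kc = model.k_currents if use_k else PotassiumCurrentModel()
    use_theta = isinstance(model, IGIFParamSet)
    if use_theta:
        beta = np.asarray(model.theta_steps, dtype=float)
        edges = np.asarray(model.bin_edges, dtype=float)
        tau_theta = model.tau_theta
    else:
        beta = np.zeros(1)
        edges = np.array([-1e9, 1e9])
        tau_theta = 1.0
    return dict(
        C=model.C, gl=model.g_l, El=model.E_l,
        eta_w=np.asarray(model.eta.weights, dtype=float),
        eta_tau=np.asarray(model.eta.timescales, dtype=float),
        gam_w=np.asarray(model.gamma.weights, dtype=float),
        gam_tau=np.asarray(model.gamma.timescales, dtype=float),
        VT=model.V_T_star, DV=model.DeltaV, lam0=model.lambda_0,
        Vreset=model.V_reset, Tref=model.T_ref,
        use_k=use_k, gA=kc.g_A_bar, gK=kc.g_K_bar, EK=kc.E_K, tauh=kc.tau_h,
        mA=kc.m_gate.A, mk=kc.m_gate.k, mV=kc.m_gate.V_star,
        hA=kc.h_gate.A, hk=kc.h_gate.k, hV=kc.h_gate.V_star,
        nA=kc.n_gate.A, nk=kc.n_gate.k, nV=kc.n_gate.V_star,
        use_theta=use_theta, theta_beta=beta, theta_edges=edges,
        tau_theta=tau_theta,
    )


def simulate(
    model: GIFParamSet,
    I: np.ndarray,
    dt: float = 0.1,
    seed: Optional[int] = None,
    mode: str = "stochastic",
    spike_times: Optional[Sequence[float]] = None,
    V0: Optional[float] = None,
    h0: Optional[float] = None,
    g_syn: Optional[np.ndarray] = None,
    E_syn_rev: float = -76.7,
) -> SimResult:
    """Forward-simulate a GIF/aGIF/iGIF neuron.

    Parameters
    ----------
    model : GIFParamSet | AGIFParamSet | IGIFParamSet
    I : ndarray
        Injected current, pA, sampled at ``dt``.
    dt : float
        Euler step, ms (0.1 by default, matching a 10 kHz recording).
    seed : int, optional
        RNG seed for the escape-rate spiking; required in stochastic mode.
    mode : "stochastic" | "spikes_clamped"
        In ``spikes_clamped`` mode the given ``spike_times`` (ms) are
        forced and only the subthreshold voltage is integrated — used to
        reconstruct the voltage for training-set evaluation and threshold
        fitting.
    g_syn : ndarray, optional
        Synaptic conductance trace, nS; adds a current
        -g_syn (V - E_syn_rev) to the subthreshold equation.
    """
    I = np.ascontiguousarray(I, dtype=float)
    if I.ndim != 1:
        raise ValueError("I must be 1-D")
    if not np.all(np.isfinite(I)):
        raise ValueError("I must be finite")
    if g_syn is None:
        g_syn = np.zeros_like(I)
    else:
        g_syn = np.ascontiguousarray(g_syn, dtype=float)
        if g_syn.shape != I.shape:
            raise ValueError("g_syn must match I in length")

    if mode == "spikes_clamped":
        if spike_times is None:
            raise ValueError("spikes_clamped mode requires spike_times")
        forced = np.asarray(np.rint(np.asarray(spike_times, dtype=float) / dt),
                            dtype=np.int64)
        if np.any(forced < 0) or np.any(forced >= I.size):
            raise ValueError("forced spike times outside the trace")
        use_forced = True
        seed_val = 0
    elif mode == "stochastic":
        if seed is None:
            raise ValueError("stochastic mode requires a seed")
        forced = np.empty(0, dtype=np.int64)
        use_forced = False
        seed_val = int(seed) % (2**31)
    else:
        raise ValueError(f"unknown mode {mode!r}")

    if V0 is None:
        V0 = model.E_l
    if h0 is None:
        if isinstance(model, AGIFParamSet):
            h0 = float(equilibrium_gate(V0, model.k_currents.h_gate))
        else:
            h0 = 1.0

    ka = _kernel_args(model)
    V, h, th, eta_tr, gam_tr, spk_idx = integrate_gif(
        I, g_syn, dt,
        ka["C"], ka["gl"], ka["El"], E_syn_rev,
        ka["eta_w"], ka["eta_tau"], ka["gam_w"], ka["gam_tau"],
        ka["VT"], ka["DV"], ka["lam0"], ka["Vreset"], ka["Tref"],
        ka["use_k"], ka["gA"], ka["gK"], ka["EK"], ka["tauh"],
        ka["mA"], ka["mk"], ka["mV"], ka["hA"], ka["hk"], ka["hV"],
        ka["nA"], ka["nk"], ka["nV"],
        ka["use_theta"], ka["theta_beta"], ka["theta_edges"], ka["tau_theta"],
        float(V0), float(h0),
        forced, use_forced, seed_val,
    )
    return SimResult(V=V, spikes=spk_idx * dt, h=h, eta_sum=eta_tr,
                     gamma_sum=gam_tr, theta=th, dt=dt)
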