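"""Nondimensional toy LIF neuron with an inactivating potassium current.

A leaky integrate-and-fire neuron augmented with I_A, nondimensionalized
with respect to the membrane time constant tau_mem = C/g_l and the leak
conductance g_l:

    dV/dt = E_l - V - g_A' m_inf(V) h (V - E_K) + V_inj(t)

with t in units of tau_mem, g_A' = g_A_bar/g_l the effective conductance,
and V_inj = I_inj/g_l the effective input (mV).  Spiking is a
deterministic threshold crossing at V_T with an instant reset; the h gate
relaxes toward h_inf(V) with effective time constant tau_h' =
tau_h/tau_mem.  Optional white background current noise (per neuron,
independent) makes population runs stochastic.

This model isolates how I_A delays and desynchronizes spiking: from
hyperpolarized initial voltages the h gate starts de-inactivated, so I_A
transiently opposes depolarization until it inactivates, lengthening and
jittering first-spike latencies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .kinetics import FIVE_HT_H_GATE, FIVE_HT_M_GATE, GatingParams, equilibrium_gate

__all__ = ["ToyLIFParams", "ToyResult", "simulate_toy", "lif_latency_closed_form"]


@dataclass(frozen=True)
class ToyLIFParams:
    """Nondimensional toy-model parameters (voltages kept on the mV scale)."""

    E_l_nd: float = -70.0
    E_K_nd: float = -101.0
    g_A_eff: float = 10.0  # g_A_bar / g_l, reference 5-HT-like value
    tau_h_eff: float = 1.2  # tau_h / tau_mem, reference 5-HT-like value
    V_T: float = -45.0
    V_reset: float = -70.0
    m_gate: GatingParams = FIVE_HT_M_GATE
    h_gate: GatingParams = FIVE_HT_H_GATE

    def __post_init__(self) -> None:
        if self.g_A_eff < 0:
            raise ValueError("g_A_eff must be non-negative")
        if self.tau_h_eff <= 0:
            raise ValueError("tau_h_eff must be positive")


@dataclass(frozen=True)
class ToyResult:
    """Population toy-model run: example trace plus per-neuron first spikes."""

    V: np.ndarray  # (n_neurons, n_steps) voltage traces
    first_spike_latency: np.ndarray  # (n_neurons,) in tau_mem units; NaN if none
    dt: float  # tau_mem units

    @property
    def latency(self) -> Optional[float]:
        """First-spike latency of neuron 0 (tau_mem units), or None."""
        v = float(self.first_spike_latency[0])
        return None if np.isnan(v) else v


def lif_latency_closed_form(params: ToyLIFParams, V_inj: float, V0: float) -> float:
    """First-spike latency of the plain LIF (g_A' = 0), tau_mem units.

    V relaxes toward V_inf = E_l + V_inj; the threshold is reached after
    ln[(V_inf - V0)/(V_inf - V_T)].  Returns inf if V_inf <= V_T.
    """
    V_inf = params.E_l_nd + V_inj
    if V_inf <= params.V_T:
        return float("inf")
    return float(np.log((V_inf - V0) / (V_inf - params.V_T)))


def simulate_toy(
    params: ToyLIFParams,
    V_inj: np.ndarray,
    V0: float,
    dt: float = 0.001,
    n_neurons: int = 1,
    noise_sd: float = 0.0,
    seed: Optional[int] = None,
    record_V: bool = True,
) -> ToyResult:
    """Euler-integrate the toy model (dt in units of tau_mem; default 0.001).

    ``V_inj`` is the effective input trace (mV) sampled at ``dt``; the h
    gate is initialized at h_inf(V0).  With ``n_neurons > 1`` the same
    input drives a population that differs only through independent white
    background noise of standard deviation ``noise_sd`` (mV, per sqrt of
    nondimensional time).
    """
    V_inj = np.asarray(V_inj, dtype=float)
    if V_inj.ndim != 1:
        raise ValueError("V_inj must be a 1-D trace")
    if noise_sd > 0 and seed is None:
        raise ValueError("noisy runs require a seed")
    rng = np.random.default_rng(seed)
    n_steps = V_inj.size

    V = np.full(n_neurons, float(V0))
    h = np.full(n_neurons, float(equilibrium_gate(V0, params.h_gate)))
    first = np.full(n_neurons, np.nan)
    V_rec = np.empty((n_neurons, n_steps)) if record_V else np.empty((n_neurons, 0))

    sq = noise_sd * np.sqrt(dt)
    for i in range(n_steps):
        if record_V:
            V_rec[:, i] = V
        m_inf = equilibrium_gate(V, params.m_gate)
        dV = (params.E_l_nd - V
              - params.g_A_eff * m_inf * h * (V - params.E_K_nd)
              + V_inj[i]) * dt
        if noise_sd > 0:
            dV = dV + sq * rng.standard_normal(n_neurons)
        h_inf = equilibrium_gate(V, params.h_gate)
        h = h + (h_inf - h) * dt / params.tau_h_eff
        V = V + dV
        crossed = V >= params.V_T
        if crossed.any():
            newly = crossed & np.isnan(first)
            first[newly] = (i + 1) * dt
            V[crossed] = params.V_reset

    return ToyResult(V=V_rec, first_spike_latency=first, dt=dt)
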