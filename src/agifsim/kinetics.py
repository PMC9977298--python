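"""Voltage-gated potassium currents of dorsal raphe 5-HT neurons.

Serotonergic neurons of the dorsal raphe express a prominent transient
(A-type, inactivating) potassium current, ``I_A``, alongside a smaller
non-inactivating component, ``I_K``.  Both are described with
Hodgkin-Huxley-style gating: the activation gates (m for I_A, n for I_K)
are assumed instantaneous, while the single inactivation gate h of I_A
relaxes with a voltage-independent time constant ``tau_h``.

Gating curves are scaled Boltzmann functions

    x_inf(V) = A / (1 + exp(-k (V - V*)))

normalized to a reference voltage during characterization, hence the
scale factor ``A`` need not be 1.  This module provides the gate and
current evaluations used by the neuron models, plus the voltage-clamp
characterization operators (Boltzmann fitting of activation/inactivation
curves and monoexponential fitting of the inactivation decay).

Units package-wide: mV, ms, pA, nS, pF.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import curve_fit, least_squares

__all__ = [
    "GatingParams",
    "PotassiumCurrentModel",
    "TransientCurrentSummary",
    "GatingFitResult",
    "equilibrium_gate",
    "potassium_currents",
    "update_h",
    "fit_gating_params",
    "characterize_transient_current",
    "FIVE_HT_M_GATE",
    "FIVE_HT_H_GATE",
    "FIVE_HT_N_GATE",
    "E_K_ROOM",
    "E_K_PHYSIO",
]

# Reversal potential of potassium: room-temperature recording conditions,
# and the value used for fits to near-physiological-temperature data.
E_K_ROOM = -101.0
E_K_PHYSIO = -89.1


@dataclass(frozen=True)
class GatingParams:
    """Scaled-Boltzmann parameters of one gate.

    Attributes
    ----------
    A : float
        Dimensionless scale factor (> 0).  Because measured gating curves
        are normalized to a reference voltage rather than their asymptote,
        A is generally not 1.
    k : float
        Slope, mV^-1.  Positive for activation gates, negative for
        inactivation gates.
    V_star : float
        Half-activation voltage, mV; the gate evaluates to A/2 there.
    """

    A: float
    k: float
    V_star: float

    def __post_init__(self) -> None:
        if not self.A > 0:
            raise ValueError(f"gate scale A must be positive, got {self.A}")

    def __call__(self, V):
        return equilibrium_gate(V, self)


# Gating parameters measured in 5-HT neurons (scaled Boltzmann fits to
# normalized voltage-clamp conductance curves).
FIVE_HT_M_GATE = GatingParams(A=1.61, k=0.0985, V_star=-23.7)
FIVE_HT_H_GATE = GatingParams(A=1.03, k=-0.165, V_star=-59.2)
FIVE_HT_N_GATE = GatingParams(A=1.55, k=0.216, V_star=-24.3)


@dataclass(frozen=True)
class PotassiumCurrentModel:
    """I_A + I_K model: maximal conductances, reversal, h kinetics, gates.

    I_A = g_A_bar * m_inf(V) * h * (V - E_K)
    I_K = g_K_bar * n_inf(V) * (V - E_K)
    dh/dt = (h_inf(V) - h) / tau_h
    """

    g_A_bar: float = 5.0
    g_K_bar: float = 1.6
    E_K: float = E_K_ROOM
    tau_h: float = 42.9
    m_gate: GatingParams = FIVE_HT_M_GATE
    h_gate: GatingParams = FIVE_HT_H_GATE
    n_gate: GatingParams = FIVE_HT_N_GATE

    def __post_init__(self) -> None:
        if self.g_A_bar < 0 or self.g_K_bar < 0:
            raise ValueError("maximal conductances must be non-negative")
        if not self.tau_h > 0:
            raise ValueError("tau_h must be positive")


@dataclass(frozen=True)
class TransientCurrentSummary:
    """Summary of a leak-subtracted voltage-step current response."""

    peak_amplitude: float  # pA
    peak_latency: float  # ms after step onset
    steady_state_amplitude: float  # pA
    tau_inact: Optional[float]  # ms; None when no decay phase exists


@dataclass(frozen=True)
class GatingFitResult:
    """Result of a scaled-Boltzmann fit, with convergence diagnostics."""

    params: GatingParams
    residual_norm: float
    converged: bool
    message: str = ""


def equilibrium_gate(V, g: GatingParams):
    """Equilibrium gate fraction x_inf(V) = A / (1 + exp(-k (V - V*))).

    Total function of voltage; vectorizes over ``V``.
    """
    V = np.asarray(V, dtype=float)
    with np.errstate(over="ignore"):  # exp overflow -> gate saturates at 0
        out = g.A / (1.0 + np.exp(-g.k * (V - g.V_star)))
    return out if out.ndim else float(out)


def potassium_currents(V, h, model: PotassiumCurrentModel):
    """Instantaneous (I_A, I_K) in pA at voltage ``V`` and h-state ``h``.

    The m and n gates are instantaneous, so only the h state is carried.
    Both currents vanish at V = E_K (zero driving force), and I_A vanishes
    whenever h = 0.
    """
    drive = np.asarray(V, dtype=float) - model.E_K
    I_A = model.g_A_bar * equilibrium_gate(V, model.m_gate) * h * drive
    I_K = model.g_K_bar * equilibrium_gate(V, model.n_gate) * drive
    return I_A, I_K


def update_h(h, V, dt: float, model: PotassiumCurrentModel):
    """Advance the inactivation gate by ``dt`` with the exponential integrator.

    h' = h_inf(V) + (h - h_inf(V)) exp(-dt / tau_h)

    Exact for constant V over the step; unconditionally stable.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    h_inf = equilibrium_gate(V, model.h_gate)
    return h_inf + (h - h_inf) * np.exp(-dt / model.tau_h)


def fit_gating_params(
    V_grid: Sequence[float],
    normalized_conductance: Sequence[float],
    V_ref: Optional[float] = None,
) -> GatingFitResult:
    """Least-squares fit of the scaled Boltzmann to a normalized gating curve.

    Parameters
    ----------
    V_grid : array-like
        Command voltages, mV; at least 4 distinct values spanning the
        transition region.
    normalized_conductance : array-like
        g_inf(V) / g_inf(V_ref) samples.
    V_ref : float, optional
        Reference voltage used for normalization (metadata only; the fit
        itself is unconstrained).

    Returns
    -------
    GatingFitResult
        Fitted parameters with the residual norm.  Degenerate inputs (no
        transition) or non-convergence produce ``converged=False`` rather
        than raising.
    """
    V = np.asarray(V_grid, dtype=float)
    y = np.asarray(normalized_conductance, dtype=float)
    if V.shape != y.shape or V.ndim != 1:
        raise ValueError("V_grid and normalized_conductance must be 1-D and equal length")
    if np.unique(V).size < 4:
        raise ValueError("need at least 4 distinct voltages")

    span = y.max() - y.min()
    fallback = GatingParams(A=max(y.max(), 1e-12) or 1.0, k=1e-6, V_star=float(np.mean(V)))
    if span <= 1e-12 * max(1.0, abs(y.max())):
        return GatingFitResult(
            params=fallback, residual_norm=float(np.linalg.norm(y - np.mean(y))),
            converged=False, message="no transition in samples (constant input)")

    # Seed: k sign from the empirical slope, V* at the half-range crossing.
    order = np.argsort(V)
    Vs, ys = V[order], y[order]
    slope_sign = 1.0 if ys[-1] >= ys[0] else -1.0
    half = ys.min() + span / 2.0
    idx = int(np.argmin(np.abs(ys - half)))
    v_half = Vs[idx]
    k0 = slope_sign * 4.0 * (span / max(Vs[-1] - Vs[0], 1e-9))
    A0 = y.max() if slope_sign > 0 else y.max()

    def boltz(v, A, k, v_star):
        return A / (1.0 + np.exp(-k * (v - v_star)))

    try:
        popt, _ = curve_fit(
            boltz, V, y, p0=[A0, k0, v_half],
            bounds=([1e-9, -10.0, V.min() - 200.0], [np.inf, 10.0, V.max() + 200.0]),
            maxfev=20000,
        )
    except RuntimeError as err:
        return GatingFitResult(params=fallback, residual_norm=float("nan"),
                               converged=False, message=str(err))

    resid = y - boltz(V, *popt)
    return GatingFitResult(
        params=GatingParams(A=float(popt[0]), k=float(popt[1]), V_star=float(popt[2])),
        residual_norm=float(np.linalg.norm(resid)),
        converged=True,
    )


def characterize_transient_current(
    trace: Sequence[float],
    dt: float,
    step_onset: float = 0.0,
    steady_state_fraction: float = 0.1,
) -> TransientCurrentSummary:
    """Summarize a leak-subtracted current response to a voltage step.

    Peak = maximum after onset; latency = argmax - onset; steady state =
    mean over the final ``steady_state_fraction`` of the trace; the
    inactivation time constant comes from a 3-parameter monoexponential
    least-squares fit a*exp(-t/tau)+c to the decay phase (peak to end),
    with c seeded at the steady-state estimate.

    When there is no decay (steady state >= peak), ``tau_inact`` is None.
    """
    I = np.asarray(trace, dtype=float)
    if I.ndim != 1 or I.size < 10:
        raise ValueError("trace must be 1-D with at least 10 samples")
    t = np.arange(I.size) * dt
    post = t >= step_onset
    if not post.any():
        raise ValueError("step_onset beyond end of trace")
    i0 = int(np.argmax(post))
    i_peak = i0 + int(np.argmax(I[i0:]))
    peak = float(I[i_peak])
    latency = float(t[i_peak] - step_onset)

    n_ss = max(int(round(steady_state_fraction * I.size)), 3)
    steady = float(np.mean(I[-n_ss:]))

    tau: Optional[float] = None
    decay = I[i_peak:]
    if peak > steady + 1e-12 and decay.size >= 10:
        s = np.arange(decay.size) * dt

        def resid(p):
            a, tau_, c = p
            return a * np.exp(-s / tau_) + c - decay

        # tau seeded at the time to decay ~63% of (peak - steady)
        target = steady + (peak - steady) * np.exp(-1.0)
        below = np.nonzero(decay <= target)[0]
        tau0 = float(s[below[0]]) if below.size else float(s[-1] / 3.0)
        tau0 = max(tau0, dt)
        sol = least_squares(
            resid, x0=[peak - steady, tau0, steady],
            bounds=([-np.inf, dt * 1e-3, -np.inf], [np.inf, np.inf, np.inf]),
        )
        if sol.success and sol.x[1] > 0:
            tau = float(sol.x[1])

    return TransientCurrentSummary(
        peak_amplitude=peak,
        peak_latency=latency,
        steady_state_amplitude=steady,
        tau_inact=tau,
    )
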