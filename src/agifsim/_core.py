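"""Numba kernels for Euler integration of GIF-family neuron models.

One kernel covers GIF, aGIF and iGIF: the potassium currents and the
voltage-coupled threshold are switched on by flags.  Spike-triggered
filters (adaptation current eta and threshold movement gamma) are sums of
exponentials, carried as per-timescale state variables that decay each
step and are incremented at spikes — equivalent to summing the filter
over all past spike times, but O(1) per step.

Conventions (shared with the fitting module, which must match exactly):
- state at sample i produces V[i+1] via forward Euler;
- the escape rate is evaluated from the state at sample i and a spike is
  drawn in bin i with probability 1 - exp(-lambda dt);
- a spike at sample s contributes w*exp(-(k-s)*dt/tau) to a filter at
  samples k > s (no instantaneous self-interaction);
- after a spike the voltage is clamped at V_reset for the absolute
  refractory period T_ref, during which no spikes can occur but h and the
  filters keep evolving.
"""

import numpy as np
from numba import njit

__all__ = ["integrate_gif"]


@njit(cache=True)
def _gate(V, A, k, Vstar):
    return A / (1.0 + np.exp(-k * (V - Vstar)))


@njit(cache=True)
def _theta_inf(V, beta, edges):
    # piecewise constant over [edges[j], edges[j+1]); clamped outside
    n = beta.shape[0]
    if V < edges[1]:
        return beta[0]
    for j in range(1, n):
        if V < edges[j + 1]:
            return beta[j]
    return beta[n - 1]


@njit(cache=True)
def integrate_gif(
    I, g_syn, dt,
    C, gl, El, E_rev,
    eta_w, eta_tau, gam_w, gam_tau,
    VT, DV, lam0, Vreset, Tref,
    use_k, gA, gK, EK, tauh,
    mA, mk, mV, hA, hk, hV, nA, nk, nV,
    use_theta, theta_beta, theta_edges, tau_theta,
    V0, h0,
    forced, use_forced, seed,
):
    """Integrate one neuron.  Returns (V, h, theta, eta_sum, gamma_sum,
    spike_indices)."""
    N = I.shape[0]
    V = np.empty(N)
    h = np.empty(N)
    th = np.empty(N)
    eta_tr = np.empty(N)
    gam_tr = np.empty(N)
    spikes = np.empty(N, dtype=np.int64)
    n_spk = 0

    if not use_forced:
        np.random.seed(seed)

    n_eta = eta_w.shape[0]
    n_gam = gam_w.shape[0]
    z_eta = np.zeros(n_eta)
    z_gam = np.zeros(n_gam)
    d_eta = np.empty(n_eta)
    d_gam = np.empty(n_gam)
    for j in range(n_eta):
        d_eta[j] = np.exp(-dt / eta_tau[j])
    for j in range(n_gam):
        d_gam[j] = np.exp(-dt / gam_tau[j])
    d_h = np.exp(-dt / tauh) if use_k else 1.0
    a_th = (1.0 - np.exp(-dt / tau_theta)) if use_theta else 0.0

    n_ref = int(np.rint(Tref / dt))
    ref_until = -1  # last sample index of the current refractory hold

    V[0] = V0
    h[0] = h0
    th[0] = 0.0
    fptr = 0  # next forced-spike index

    for i in range(N):
        e_sum = 0.0
        for j in range(n_eta):
            e_sum += z_eta[j]
        g_sum = 0.0
        for j in range(n_gam):
            g_sum += z_gam[j]
        eta_tr[i] = e_sum
        gam_tr[i] = g_sum

        # spike decision in bin i
        spiked = False
        if use_forced:
            if fptr < forced.shape[0] and forced[fptr] == i:
                spiked = True
                fptr += 1
        elif i > ref_until:
            ex = (V[i] - VT - g_sum - th[i]) / DV
            if ex > 30.0:
                ex = 30.0
            lam = lam0 * np.exp(ex)  # Hz
            p = 1.0 - np.exp(-lam * dt * 1e-3)
            if np.random.random() < p:
                spiked = True

        if spiked:
            spikes[n_spk] = i
            n_spk += 1
            ref_until = i + n_ref
            for j in range(n_eta):
                z_eta[j] += eta_w[j]
            for j in range(n_gam):
                z_gam[j] += gam_w[j]

        if i == N - 1:
            break

        # subthreshold update i -> i+1
        if i < ref_until or spiked:
            V[i + 1] = Vreset
        else:
            dVdt = -gl * (V[i] - El) - e_sum + I[i]
            if use_k:
                drive = V[i] - EK
                dVdt -= gA * _gate(V[i], mA, mk, mV) * h[i] * drive
                dVdt -= gK * _gate(V[i], nA, nk, nV) * drive
            dVdt -= g_syn[i] * (V[i] - E_rev)
            V[i + 1] = V[i] + dt * dVdt / C
            if np.isnan(V[i + 1]):
                raise ValueError("NaN in voltage state during integration")

        if use_k:
            hinf = _gate(V[i], hA, hk, hV)
            h[i + 1] = hinf + (h[i] - hinf) * d_h
        else:
            h[i + 1] = h[i]

        if use_theta:
            th[i + 1] = th[i] + a_th * (_theta_inf(V[i], theta_beta, theta_edges) - th[i])
        else:
            th[i + 1] = 0.0

        for j in range(n_eta):
            z_eta[j] *= d_eta[j]
        for j in range(n_gam):
            z_gam[j] *= d_gam[j]

    return V, h, th, eta_tr, gam_tr, spikes[:n_spk].copy()
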