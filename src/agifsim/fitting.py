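"""Two-stage GIF-family parameter estimation and recording QC.

Stage 1 (subthreshold): ordinary least squares of the observed voltage
derivative dV/dt on {V, 1, I_inj, spike-triggered exponential basis} —
plus, for the aGIF, the two potassium-current regressors
m_inf(V) h(t) (V - E_K) and n_inf(V) (V - E_K) with gating and tau_h held
fixed at their voltage-clamp values, so the maximal conductances enter
linearly.  Samples in a small window around each spike (cell-type
dependent: -1.5/+6.5 ms for 5-HT, -1.5/+4.0 ms for SOM and mPFC) are
excluded.

Stage 2 (threshold): maximum likelihood of the observed spike train under
the escape-rate model, over the natural parameters (1/DeltaV, V_T*/DeltaV,
gamma_j/DeltaV and, for the iGIF, theta_j/DeltaV).  The log-likelihood is
concave in these parameters; Newton-type ascent converges globally.  The
subthreshold voltage is first reconstructed with spikes clamped to the
data.

All discrete conventions (forward Euler, filter increments at the spike
bin taking effect one sample later, refractory clamping) match the
simulation kernel exactly, so fits to surrogate data generated by the
package's own models are consistent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import minimize
from scipy.signal import lfilter
from scipy.stats import pearsonr

from .kinetics import PotassiumCurrentModel, equilibrium_gate
from .metrics import SpikeTrainSet, intrinsic_reliability
from .models import (AGIFParamSet, DEFAULT_FILTER_TIMESCALES, FilterCoeffs,
                     GIFParamSet, IGIFParamSet, simulate)
from .synth import Recording

__all__ = [
    "detect_spikes",
    "SubthresholdFit",
    "ThresholdFit",
    "QCResult",
    "fit_subthreshold",
    "fit_threshold",
    "fit_gif",
    "qc_recording",
    "EXCLUSION_WINDOWS",
]

#: Per-spike exclusion windows (pre, post), ms, by cell type.
EXCLUSION_WINDOWS: Dict[str, Tuple[float, float]] = {
    "5-HT": (1.5, 6.5),
    "SOM": (1.5, 4.0),
    "mPFC": (1.5, 4.0),
}

_TAU_THETA_GRID = (1.0, 3.0, 5.0, 10.0, 30.0, 100.0)


def detect_spikes(V: np.ndarray, dt: float, threshold: float = 0.0,
                  min_interval: float = 2.0) -> np.ndarray:
    """Spike times (ms) as upward threshold crossings separated by >= min_interval."""
    V = np.asarray(V, dtype=float)
    above = V >= threshold
    crossings = np.nonzero(above[1:] & ~above[:-1])[0] + 1
    if crossings.size == 0:
        return np.empty(0)
    kept = [crossings[0]]
    min_bins = min_interval / dt
    for c in crossings[1:]:
        if c - kept[-1] >= min_bins:
            kept.append(c)
    return np.asarray(kept) * dt


def _basis_filtered(spike_bins: np.ndarray, n: int, dt: float,
                    timescales: Sequence[float]) -> np.ndarray:
    """Columns b_j[k] = sum over spikes s < k of exp(-(k - s) dt / tau_j).

    Matches the kernel's filter-state convention: a spike contributes from
    the *next* sample onward.
    """
    ind = np.zeros(n)
    ind[spike_bins] = 1.0
    cols = np.empty((n, len(timescales)))
    for j, tau in enumerate(timescales):
        d = np.exp(-dt / tau)
        raw = lfilter([1.0], [1.0, -d], ind)
        cols[1:, j] = d * raw[:-1]
        cols[0, j] = 0.0
    return cols


def _h_trace(V: np.ndarray, dt: float, kc: PotassiumCurrentModel) -> np.ndarray:
    """Inactivation-gate trajectory driven by the observed voltage."""
    hinf = np.asarray(equilibrium_gate(V, kc.h_gate), dtype=float)
    d = np.exp(-dt / kc.tau_h)
    h0 = hinf[0]
    z = lfilter([1.0 - d], [1.0, -d], hinf, zi=np.array([d * h0]))[0]
    h = np.empty_like(hinf)
    h[0] = h0
    h[1:] = z[:-1]
    return h


def _exclusion_mask(n: int, dt: float, spike_times: np.ndarray,
                    window: Tuple[float, float]) -> np.ndarray:
    keep = np.ones(n, dtype=bool)
    pre, post = window
    t = np.arange(n) * dt
    for t_hat in spike_times:
        keep[(t >= t_hat - pre) & (t <= t_hat + post)] = False
    return keep


@dataclass
class SubthresholdFit:
    """Stage-1 result: passive + adaptation (+ potassium conductance) params."""

    C: float
    g_l: float
    E_l: float
    eta: FilterCoeffs
    g_A_bar: Optional[float]
    g_K_bar: Optional[float]
    V_reset: float
    r_squared: float
    spike_times: List[np.ndarray]
    kind: str


def fit_subthreshold(
    rec: Recording,
    kind: str = "GIF",
    k_fixed: Optional[PotassiumCurrentModel] = None,
    exclusion_window: Optional[Tuple[float, float]] = None,
    eta_timescales: Sequence[float] = DEFAULT_FILTER_TIMESCALES,
    spike_threshold: float = 0.0,
    T_ref: Optional[float] = None,
) -> SubthresholdFit:
    """Estimate C, g_l, E_l, eta weights (and g_A_bar, g_K_bar for the aGIF)
    by OLS on the training-set voltage derivative.

    Raises on a rank-deficient design, naming the offending regressors.
    """
    if kind not in ("GIF", "aGIF", "iGIF"):
        raise ValueError(f"unknown model kind {kind!r}")
    use_k = kind == "aGIF"
    if use_k and k_fixed is None:
        k_fixed = PotassiumCurrentModel()
    if exclusion_window is None:
        exclusion_window = EXCLUSION_WINDOWS.get(rec.cell_type, (1.5, 4.0))
    dt = rec.dt
    if T_ref is None:
        T_ref = exclusion_window[1]

    names = ["V", "const", "I"] + [f"eta_tau{tau:g}" for tau in eta_timescales]
    if use_k:
        names += ["I_A_regressor", "I_K_regressor"]

    X_parts, y_parts = [], []
    all_spikes: List[np.ndarray] = []
    reset_samples: List[float] = []
    for s in range(rec.n_sweeps):
        V, I = rec.V[s], rec.I[s]
        n = V.size
        spk = detect_spikes(V, dt, threshold=spike_threshold, min_interval=T_ref)
        all_spikes.append(spk)
        spike_bins = np.asarray(np.rint(spk / dt), dtype=int)
        cols = [V, np.ones(n), I]
        cols += list(_basis_filtered(spike_bins, n, dt, eta_timescales).T)
        if use_k:
            h = _h_trace(V, dt, k_fixed)
            drive = V - k_fixed.E_K
            cols.append(equilibrium_gate(V, k_fixed.m_gate) * h * drive)
            cols.append(equilibrium_gate(V, k_fixed.n_gate) * drive)
        X = np.column_stack(cols)[:-1]
        y = np.diff(V) / dt
        keep = _exclusion_mask(n, dt, spk, exclusion_window)[:-1]
        X_parts.append(X[keep])
        y_parts.append(y[keep])
        # mean voltage one refractory period after each spike -> reset estimate
        for b in spike_bins:
            idx = b + int(round(T_ref / dt)) + 1
            if idx < n:
                reset_samples.append(V[idx])

    X = np.vstack(X_parts)
    y = np.concatenate(y_parts)
    sv = np.linalg.svd(X, compute_uv=False)
    if sv[-1] < 1e-10 * sv[0]:
        # identify degenerate columns: zero variance or duplicated direction
        bad = [names[j] for j in range(X.shape[1])
               if j != 1 and np.std(X[:, j]) < 1e-12 * (1 + np.abs(X[:, j]).max())]
        raise ValueError(
            "rank-deficient subthreshold design"
            + (f"; degenerate regressors: {bad}" if bad else f" (condition {sv[0]/sv[-1]:.2e})"))
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)

    a_V, a_1, a_I = coef[0], coef[1], coef[2]
    n_eta = len(eta_timescales)
    a_eta = coef[3:3 + n_eta]
    C = 1.0 / a_I
    g_l = -a_V * C
    E_l = a_1 * C / g_l
    eta = FilterCoeffs(weights=tuple(-a_eta * C), timescales=tuple(eta_timescales))
    g_A = g_K = None
    if use_k:
        g_A = float(-coef[3 + n_eta] * C)
        g_K = float(-coef[4 + n_eta] * C)

    resid = y - X @ coef
    r2 = float(1.0 - np.sum(resid**2) / np.sum((y - y.mean()) ** 2))
    V_reset = float(np.mean(reset_samples)) if reset_samples else E_l

    return SubthresholdFit(C=float(C), g_l=float(g_l), E_l=float(E_l), eta=eta,
                           g_A_bar=g_A, g_K_bar=g_K, V_reset=V_reset,
                           r_squared=r2, spike_times=all_spikes, kind=kind)


@dataclass
class ThresholdFit:
    """Stage-2 result: stationary threshold, sharpness, gamma (and theta)."""

    V_T_star: float
    DeltaV: float
    gamma: FilterCoeffs
    theta_steps: Optional[Tuple[float, ...]]
    bin_edges: Optional[Tuple[float, ...]]
    tau_theta: Optional[float]
    log_likelihood: float
    n_spikes: int


def _theta_features(V: np.ndarray, edges: np.ndarray, tau_theta: float,
                    dt: float) -> np.ndarray:
    """Filtered voltage-bin indicators: columns Theta_l with
    dTheta_l/dt = (ind_l(V) - Theta_l)/tau_theta (exact discretization)."""
    n_bins = edges.size - 1
    a = np.exp(-dt / tau_theta)
    cols = np.empty((V.size, n_bins))
    for l in range(n_bins):
        lo, hi = edges[l], edges[l + 1]
        if l == 0:
            ind = (V < hi).astype(float)
        elif l == n_bins - 1:
            ind = (V >= lo).astype(float)
        else:
            ind = ((V >= lo) & (V < hi)).astype(float)
        z = lfilter([1.0 - a], [1.0, -a], ind, zi=np.array([0.0]))[0]
        cols[0, l] = 0.0
        cols[1:, l] = z[:-1]
    return cols


def _threshold_mle(X: np.ndarray, is_spike: np.ndarray, w: float,
                   p0: np.ndarray) -> Tuple[np.ndarray, float]:
    """Maximize the exact per-bin Bernoulli likelihood of the spike train.

    P(spike in bin) = 1 - exp(-lambda dt) with log lambda linear in the
    parameters — a complementary-log-log model, whose log-likelihood is
    concave, so the ascent converges to the global optimum.
    """
    spk = is_spike
    non = ~is_spike

    def negll(p):
        z = np.clip(X @ p, -200.0, 200.0)
        mu = w * np.exp(z)  # expected count per bin
        mu_s = mu[spk]
        # log(1 - exp(-mu)) for spike bins; -mu elsewhere
        ll = float(np.log(-np.expm1(-np.clip(mu_s, 1e-300, None))).sum()
                   - mu[non].sum())
        mu_c = np.clip(mu_s, None, 300.0)
        g_spk = np.where(mu_s < 1e-10, 1.0 - mu_s / 2.0, mu_c / np.expm1(mu_c))
        grad = g_spk @ X[spk] - mu[non] @ X[non]
        return -ll, -grad

    res = minimize(negll, p0, jac=True, method="L-BFGS-B",
                   options={"maxiter": 1000, "ftol": 1e-14, "gtol": 1e-9})
    if not np.isfinite(res.fun):
        raise RuntimeError(f"non-finite likelihood in threshold fit: {res.message}")
    return res.x, -float(res.fun)


def fit_threshold(
    sub: SubthresholdFit,
    rec: Recording,
    kind: str = "GIF",
    k_fixed: Optional[PotassiumCurrentModel] = None,
    gamma_timescales: Sequence[float] = DEFAULT_FILTER_TIMESCALES,
    T_ref: Optional[float] = None,
    lambda_0: float = 1.0,
    rec_val: Optional[Recording] = None,
    tau_theta_grid: Sequence[float] = _TAU_THETA_GRID,
) -> ThresholdFit:
    """Maximum-likelihood estimation of V_T*, DeltaV, gamma (and theta).

    The subthreshold voltage is reconstructed with spikes clamped to the
    detected times; refractory bins are excluded from the likelihood.
    For the iGIF, theta bin edges are placed at quintiles of the
    subthreshold voltage distribution and tau_theta is chosen by grid
    search (on validation likelihood when ``rec_val`` is given, otherwise
    on training likelihood).
    """
    if kind not in ("GIF", "aGIF", "iGIF"):
        raise ValueError(f"unknown model kind {kind!r}")
    dt = rec.dt
    if T_ref is None:
        T_ref = EXCLUSION_WINDOWS.get(rec.cell_type, (1.5, 4.0))[1]
    n_ref = int(round(T_ref / dt))

    base = _reconstruction_model(sub, kind, k_fixed, T_ref)

    def _design(recording: Recording, spikes: List[np.ndarray], edges, tau_theta):
        Vs, Gs, Ths, spk_mask = [], [], [], []
        for s in range(recording.n_sweeps):
            spk = spikes[s]
            spike_bins = np.asarray(np.rint(spk / dt), dtype=int)
            res = simulate(base, recording.I[s], dt=dt, mode="spikes_clamped",
                           spike_times=spk)
            n = res.V.size
            keep = np.ones(n, dtype=bool)
            for b in spike_bins:
                keep[b + 1:min(b + n_ref + 1, n)] = False
            is_spk = np.zeros(n, dtype=bool)
            is_spk[spike_bins] = True
            G = _basis_filtered(spike_bins, n, dt, gamma_timescales)
            Vs.append(res.V[keep])
            Gs.append(G[keep])
            spk_mask.append(is_spk[keep])
            if edges is not None:
                Ths.append(_theta_features(res.V, edges, tau_theta, dt)[keep])
        V = np.concatenate(Vs)
        cols = [V[:, None], -np.ones((V.size, 1)), -np.vstack(Gs)]
        if edges is not None:
            cols.append(-np.vstack(Ths))
        return np.hstack(cols), np.concatenate(spk_mask), V

    w = lambda_0 * dt * 1e-3
    spikes_train = sub.spike_times

    def _fit_once(edges, tau_theta):
        X, is_spk, V = _design(rec, spikes_train, edges, tau_theta)
        b0 = 0.25
        p0 = np.zeros(X.shape[1])
        p0[0] = b0
        p0[1] = b0 * np.percentile(V, 95)
        p, ll = _threshold_mle(X, is_spk, w, p0)
        return p, ll, V

    if kind in ("GIF", "aGIF"):
        p, ll, _ = _fit_once(None, None)
        edges = tau_best = theta = None
    else:
        # voltage quintile edges from a first clamped reconstruction
        _, _, V_all = _fit_once(None, None)
        edges = np.quantile(V_all, [0.0, 0.2, 0.4, 0.6, 0.8, 1.0])
        edges = _strictly_increasing(edges)
        best = None
        for tau_c in tau_theta_grid:
            p_c, ll_c, _ = _fit_once(edges, tau_c)
            score = ll_c
            if rec_val is not None:
                val_spikes = [detect_spikes(rec_val.V[s], dt, min_interval=T_ref)
                              for s in range(rec_val.n_sweeps)]
                Xv, sv_mask, _ = _design(rec_val, val_spikes, edges, tau_c)
                exv = np.clip(Xv @ p_c, -700, 700)
                score = float(exv[sv_mask].sum() - (w * np.exp(exv)).sum())
            if best is None or score > best[0]:
                best = (score, tau_c, p_c, ll_c)
        _, tau_best, p, ll = best
        theta = tuple(p[2 + len(gamma_timescales):] / p[0])

    b, a = p[0], p[1]
    gamma_w = p[2:2 + len(gamma_timescales)] / b
    n_spk = int(sum(s.size for s in spikes_train))
    return ThresholdFit(
        V_T_star=float(a / b), DeltaV=float(1.0 / b),
        gamma=FilterCoeffs(weights=tuple(gamma_w), timescales=tuple(gamma_timescales)),
        theta_steps=theta,
        bin_edges=tuple(edges) if edges is not None else None,
        tau_theta=tau_best, log_likelihood=ll, n_spikes=n_spk,
    )


def _strictly_increasing(edges: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    out = edges.copy()
    for i in range(1, out.size):
        if out[i] <= out[i - 1]:
            out[i] = out[i - 1] + eps
    return out


def _reconstruction_model(sub: SubthresholdFit, kind: str,
                          k_fixed: Optional[PotassiumCurrentModel],
                          T_ref: float) -> GIFParamSet:
    fields = dict(C=sub.C, g_l=sub.g_l, E_l=sub.E_l, eta=sub.eta,
                  V_T_star=-45.0, DeltaV=2.0, V_reset=sub.V_reset, T_ref=T_ref)
    if kind == "aGIF":
        kc = k_fixed if k_fixed is not None else PotassiumCurrentModel()
        kc = PotassiumCurrentModel(
            g_A_bar=sub.g_A_bar if sub.g_A_bar is not None else kc.g_A_bar,
            g_K_bar=sub.g_K_bar if sub.g_K_bar is not None else kc.g_K_bar,
            E_K=kc.E_K, tau_h=kc.tau_h, m_gate=kc.m_gate, h_gate=kc.h_gate,
            n_gate=kc.n_gate)
        return AGIFParamSet(k_currents=kc, **fields)
    return GIFParamSet(**fields)


def fit_gif(
    rec_train: Recording,
    kind: str = "GIF",
    k_fixed: Optional[PotassiumCurrentModel] = None,
    rec_val: Optional[Recording] = None,
    **kwargs,
) -> Tuple[GIFParamSet, SubthresholdFit, ThresholdFit]:
    """Run both fitting stages and assemble a complete parameter set."""
    window = EXCLUSION_WINDOWS.get(rec_train.cell_type, (1.5, 4.0))
    sub = fit_subthreshold(rec_train, kind=kind, k_fixed=k_fixed,
                           exclusion_window=window, **kwargs)
    thr = fit_threshold(sub, rec_train, kind=kind, k_fixed=k_fixed,
                        T_ref=window[1], rec_val=rec_val)
    fields = dict(C=sub.C, g_l=sub.g_l, E_l=sub.E_l, eta=sub.eta,
                  gamma=thr.gamma, V_T_star=thr.V_T_star, DeltaV=thr.DeltaV,
                  V_reset=sub.V_reset, T_ref=window[1])
    if kind == "aGIF":
        kc = k_fixed if k_fixed is not None else PotassiumCurrentModel()
        kc = PotassiumCurrentModel(g_A_bar=sub.g_A_bar, g_K_bar=sub.g_K_bar,
                                   E_K=kc.E_K, tau_h=kc.tau_h, m_gate=kc.m_gate,
                                   h_gate=kc.h_gate, n_gate=kc.n_gate)
        model: GIFParamSet = AGIFParamSet(k_currents=kc, **fields)
    elif kind == "iGIF":
        model = IGIFParamSet(theta_steps=thr.theta_steps,
                             bin_edges=thr.bin_edges,
                             tau_theta=thr.tau_theta, **fields)
    else:
        model = GIFParamSet(**fields)
    return model, sub, thr


@dataclass(frozen=True)
class QCResult:
    include: bool
    drift_r: float
    reliability: float
    reasons: Tuple[str, ...]


def qc_recording(validation_trains: SpikeTrainSet,
                 drift_threshold: float = 0.9,
                 reliability_threshold: float = 0.1) -> QCResult:
    """Recording inclusion criteria on validation sweeps.

    Excludes cells with non-stationary firing statistics (Pearson
    correlation between spike count and sweep index above 0.9) or highly
    variable spike timing (intrinsic reliability below 0.1).
    """
    if validation_trains.n_sweeps < 3:
        raise ValueError("QC requires at least 3 validation sweeps")
    counts = validation_trains.counts().astype(float)
    if np.std(counts) < 1e-12:
        r = 0.0
    else:
        r = float(pearsonr(np.arange(counts.size), counts)[0])
    rel = intrinsic_reliability(validation_trains)
    reasons = []
    if r > drift_threshold:
        reasons.append("drift")
    if rel < reliability_threshold:
        reasons.append("unreliable")
    return QCResult(include=not reasons, drift_r=r, reliability=rel,
                    reasons=tuple(reasons))
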