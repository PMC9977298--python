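"""Stimulus generation: frozen OU noise, steps, ramps, voltage-clamp protocols.

Training and validation stimuli emulate the in vivo-like current-clamp
protocol used to constrain the neuron models: the training set is frozen
(seed-reproducible) Ornstein-Uhlenbeck noise lasting 60 s, the validation
set a different frozen OU stimulus of 10 s, each repeated across sweeps.
The OU process uses the exact discretization, so statistics are unbiased
at any dt.

Per-cell-type OU parameters (mean/SD in pA, correlation time in ms) are
package defaults chosen to drive the synthetic model banks at low
physiological rates; they are configurable everywhere they are used.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
from scipy.signal import lfilter

__all__ = [
    "OUParams",
    "StimulusProtocol",
    "TrainValProtocol",
    "CELL_TYPE_OU",
    "ou_noise",
    "make_step",
    "make_ramp",
    "vclamp_step_protocol",
    "training_validation_protocol",
]


@dataclass(frozen=True)
class OUParams:
    """Ornstein-Uhlenbeck stimulus parameters: mean, SD (pA), tau (ms)."""

    mu: float
    sigma: float
    tau: float = 3.0


#: Default OU stimulus parameters per cell type.  Means follow the relative
#: excitability of the cell types (SOM most excitable, mPFC least); SDs
#: drive the default synthetic banks in the low single-digit Hz range.
CELL_TYPE_OU: Dict[str, OUParams] = {
    "5-HT": OUParams(mu=65.0, sigma=55.0, tau=3.0),
    "SOM": OUParams(mu=15.0, sigma=30.0, tau=3.0),
    "mPFC": OUParams(mu=100.0, sigma=200.0, tau=3.0),
}


def ou_noise(mu: float, sigma: float, tau: float, duration: float, dt: float,
             seed: int) -> np.ndarray:
    """Frozen OU current trace (pA): exact discretization, stationary start.

    x_{k+1} = mu + (x_k - mu) a + sigma sqrt(1 - a^2) xi_k,  a = exp(-dt/tau)

    Identical (parameters, seed) give bitwise-identical traces.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    if duration <= 0 or dt <= 0:
        raise ValueError("duration and dt must be positive")
    n = int(round(duration / dt))
    rng = np.random.default_rng(seed)
    a = np.exp(-dt / tau)
    b = sigma * np.sqrt(1.0 - a * a)
    xi = rng.standard_normal(n)
    dev = np.empty(n)
    dev[0] = sigma * xi[0]  # stationary start
    if n > 1:
        # first-order recursion dev[k] = a dev[k-1] + b xi[k] via lfilter
        dev[1:] = lfilter([1.0], [1.0, -a], b * xi[1:], zi=np.array([a * dev[0]]))[0]
    return mu + dev


def make_step(baseline: float, amplitude: float, onset: float, duration: float,
              dt: float, total_duration: Optional[float] = None) -> np.ndarray:
    """Current step: baseline everywhere, baseline+amplitude on [onset, onset+duration)."""
    total = duration + onset if total_duration is None else total_duration
    n = int(round(total / dt))
    t = np.arange(n) * dt
    I = np.full(n, float(baseline))
    I[(t >= onset) & (t < onset + duration)] += amplitude
    return I


def make_ramp(baseline: float, slope: float, duration: float, dt: float,
              onset: float = 0.0) -> np.ndarray:
    """Ramp current: I(t) = baseline + slope * (t - onset) for t >= onset.

    ``slope`` is in pA/s, ``duration``/``dt`` in ms.
    """
    n = int(round(duration / dt))
    t = np.arange(n) * dt
    I = np.full(n, float(baseline))
    after = t >= onset
    I[after] += slope * (t[after] - onset) * 1e-3
    return I


@dataclass(frozen=True)
class StimulusProtocol:
    """Descriptor of a voltage-clamp step protocol (used by kinetics fits)."""

    hold_voltage: float = -90.0  # mV, pre-step holding potential
    step_voltages: Tuple[float, ...] = tuple(float(v) for v in range(-90, -15, 5))
    step_duration: float = 300.0  # ms
    hold_duration: float = 500.0  # ms
    dt: float = 0.1


def vclamp_step_protocol(**kwargs) -> StimulusProtocol:
    """Activation-curve voltage-step protocol (default -90..-20 mV)."""
    return StimulusProtocol(**kwargs)


@dataclass(frozen=True)
class TrainValProtocol:
    """Frozen-noise training/validation protocol for one cell type.

    60 s of frozen OU noise for training and a different 10 s frozen OU
    stimulus for validation, each repeated across sweeps.
    """

    cell_type: str
    train: np.ndarray  # pA, 60 s
    validation: np.ndarray  # pA, 10 s
    dt: float
    n_train: int
    n_val: int
    train_seed: int
    val_seed: int
    ou: OUParams


def training_validation_protocol(
    cell_type: str,
    dt: float = 0.1,
    n_train: int = 1,
    n_val: int = 9,
    seed: int = 0,
    ou: Optional[OUParams] = None,
    train_duration: float = 60_000.0,
    val_duration: float = 10_000.0,
) -> TrainValProtocol:
    """Build the frozen-OU training (60 s) / validation (10 s) protocol.

    The two stimuli are frozen with distinct seeds derived from ``seed``;
    sweeps repeat the identical trace so that trial-to-trial variability
    reflects intrinsic stochasticity only.  ``n_val >= 9`` by default so
    pairwise spike-train metrics are well defined.
    """
    if ou is None:
        if cell_type not in CELL_TYPE_OU:
            raise KeyError(f"unknown cell type {cell_type!r}; give ou= explicitly")
        ou = CELL_TYPE_OU[cell_type]
    ss = np.random.SeedSequence(seed)
    train_seed, val_seed = [int(s) for s in ss.generate_state(2) >> 1]
    train = ou_noise(ou.mu, ou.sigma, ou.tau, train_duration, dt, train_seed)
    val = ou_noise(ou.mu, ou.sigma, ou.tau, val_duration, dt, val_seed)
    return TrainValProtocol(cell_type=cell_type, train=train, validation=val,
                            dt=dt, n_train=n_train, n_val=n_val,
                            train_seed=train_seed, val_seed=val_seed, ou=ou)
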