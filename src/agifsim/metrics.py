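"""Model-performance metrics: subthreshold R², Md* spike-train similarity,
and intrinsic reliability.

Md* compares a set of model-predicted spike trains against repeated
validation sweeps recorded under the same frozen stimulus:

    Md* = 2 n_dm / (n_dd* + n_mm)

where n_dm counts model spikes falling within a +/- 8 ms window of a
data spike, and n_dd*, n_mm are the corresponding within-set coincidence
counts.  All three terms are means of per-pair coincidence counts with
the analytic chance expectation n_pred (1 - exp(-2 Delta n_ref / T))
subtracted (exact for a Poisson reference train), taken over every
ordered sweep pair (within-set terms include the trivial self-pairs);
the within-data term is additionally floored at zero (the small-sample
correction).  Under
this estimator the chance level is 0 (independent Poisson predictions)
and a model whose predicted set reproduces the data set exactly scores 1
by construction.

Intrinsic reliability is the mean pairwise coincidence factor Gamma
across distinct sweeps of the data itself, at the same timing precision;
it bounds how well any model can do and feeds the recording QC.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np

__all__ = [
    "SpikeTrainSet",
    "r_squared_subthreshold",
    "coincident_spikes",
    "md_star",
    "intrinsic_reliability",
]

#: Default spike-timing precision (ms), set by the relationship between
#: precision and intrinsic reliability in the recordings.
DEFAULT_PRECISION = 8.0


@dataclass(frozen=True)
class SpikeTrainSet:
    """Spike times (ms) for repeated sweeps of a common stimulus."""

    trains: tuple
    duration: float

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "trains",
            tuple(np.sort(np.asarray(tr, dtype=float)) for tr in self.trains))
        for tr in self.trains:
            if tr.size and (tr[0] < 0 or tr[-1] >= self.duration):
                raise ValueError("spike times must lie in [0, duration)")

    @property
    def n_sweeps(self) -> int:
        return len(self.trains)

    def counts(self) -> np.ndarray:
        return np.array([tr.size for tr in self.trains])


def r_squared_subthreshold(
    predicted_dVdt: np.ndarray,
    observed_dVdt: np.ndarray,
    spike_times: Sequence[float],
    dt: float,
    window: Sequence[float] = (1.5, 6.5),
) -> Optional[float]:
    """R² of predicted vs observed dV/dt, excluding per-spike windows.

    Each spike masks samples in [t_hat - window[0], t_hat + window[1]].
    Returns None when the retained observation has zero variance.
    """
    pred = np.asarray(predicted_dVdt, dtype=float)
    obs = np.asarray(observed_dVdt, dtype=float)
    if pred.shape != obs.shape or pred.ndim != 1:
        raise ValueError("traces must be 1-D and aligned")
    keep = np.ones(obs.size, dtype=bool)
    t = np.arange(obs.size) * dt
    pre, post = window
    for t_hat in np.asarray(spike_times, dtype=float):
        keep &= ~((t >= t_hat - pre) & (t <= t_hat + post))
    o, p = obs[keep], pred[keep]
    ss_tot = np.sum((o - o.mean()) ** 2)
    if ss_tot <= 0:
        return None
    return float(1.0 - np.sum((o - p) ** 2) / ss_tot)


def coincident_spikes(reference: np.ndarray, predicted: np.ndarray,
                      precision: float) -> int:
    """Number of ``predicted`` spikes within +/- precision of any
    ``reference`` spike.  Both trains must be sorted."""
    if reference.size == 0 or predicted.size == 0:
        return 0
    pos = np.searchsorted(reference, predicted)
    left = np.clip(pos - 1, 0, reference.size - 1)
    right = np.clip(pos, 0, reference.size - 1)
    d = np.minimum(np.abs(predicted - reference[left]),
                   np.abs(predicted - reference[right]))
    return int(np.count_nonzero(d <= precision))


def _chance(reference: np.ndarray, predicted: np.ndarray, precision: float,
            T: float) -> float:
    # exact expected coincidences when the reference train is a homogeneous
    # Poisson process independent of the prediction:
    # n_pred * (1 - exp(-2 Delta n_ref / T))
    return predicted.size * -np.expm1(-2.0 * precision * reference.size / T)


def _mean_corrected_all_pairs(X: SpikeTrainSet, Y: SpikeTrainSet,
                              precision: float) -> float:
    """Mean over all ordered (x, y) sweep pairs of (coincidences - chance)."""
    T = X.duration
    total = 0.0
    for a in X.trains:
        for b in Y.trains:
            total += coincident_spikes(a, b, precision) - _chance(a, b, precision, T)
    return total / (X.n_sweeps * Y.n_sweeps)


def md_star(data: SpikeTrainSet, model: SpikeTrainSet,
            precision: float = DEFAULT_PRECISION) -> float:
    """Chance-corrected spike-train similarity Md* (1 = perfect, 0 = chance)."""
    if data.n_sweeps < 2 or model.n_sweeps < 2:
        raise ValueError("Md* requires at least 2 sweeps on each side")
    if abs(data.duration - model.duration) > 1e-9:
        raise ValueError("data and model durations must match")
    n_dm = _mean_corrected_all_pairs(data, model, precision)
    n_dd = max(_mean_corrected_all_pairs(data, data, precision), 0.0)
    n_mm = _mean_corrected_all_pairs(model, model, precision)
    denom = n_dd + n_mm
    if denom <= 0:
        return 0.0
    return float(2.0 * n_dm / denom)


def intrinsic_reliability(data: SpikeTrainSet,
                          precision: float = DEFAULT_PRECISION) -> float:
    """Mean pairwise coincidence factor Gamma over distinct sweep pairs.

    Gamma_ab = (n_coinc - chance) / ((n_a + n_b)/2 - chance); 1 for
    identical sweeps, ~0 for independent Poisson sweeps.
    """
    if data.n_sweeps < 2:
        raise ValueError("reliability requires at least 2 sweeps")
    T = data.duration
    vals = []
    trains = data.trains
    for i in range(len(trains)):
        for j in range(i + 1, len(trains)):
            a, b = trains[i], trains[j]
            chance = _chance(a, b, precision, T)
            denom = 0.5 * (a.size + b.size) - chance
            if denom <= 0:
                continue
            vals.append((coincident_spikes(a, b, precision) - chance) / denom)
    if not vals:
        return 0.0
    return float(np.mean(vals))
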