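"""Synthetic-data generator: model banks and surrogate recordings.

The generator emulates the structure of real patch-clamp datasets:
per-cell sweep sets of (t, V, I) with a known stimulus, cell-type-specific
membrane parameters (matching the measured means and spreads of dorsal
raphe 5-HT, dorsal raphe SOM, and mPFC L5 pyramidal neurons), and 5-HT
potassium-current gating fixed at the voltage-clamp values.  Banks of
parameter sets with realistic neuron-to-neuron heterogeneity stand in for
banks of fitted single-cell models when the experimental recordings are
not available.

Cell-type templates (means):

==========  ======== ======== ===========================================
parameter    5-HT     SOM      mPFC
==========  ======== ======== ===========================================
R (GOhm)     1.16     1.07     0.188
C (pF)       67.0     43.5     160.6
==========  ======== ======== ===========================================

SOM heterogeneity specs use larger coefficients of variation than 5-HT,
matching the reported variance differences in excitability (gain and
adaptation) between the two cell types.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Union

import numpy as np

from .kinetics import PotassiumCurrentModel
from .models import AGIFParamSet, FilterCoeffs, GIFParamSet, simulate
from .stimuli import TrainValProtocol

__all__ = [
    "Recording",
    "ModelBank",
    "HeterogeneitySpec",
    "cell_template",
    "generate_bank",
    "generate_surrogate_recording",
    "CELL_TEMPLATES",
    "CELL_HETEROGENEITY",
]


@dataclass
class Recording:
    """Per-cell sweep set of paired voltage/current traces.

    ``V`` and ``I`` are (n_sweeps, n_samples) arrays at time step ``dt``
    (ms); training and validation sweeps are stored as separate
    recordings in practice.
    """

    V: np.ndarray
    I: np.ndarray
    dt: float
    cell_type: str = "5-HT"
    metadata: Dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.V = np.atleast_2d(np.asarray(self.V, dtype=float))
        self.I = np.atleast_2d(np.asarray(self.I, dtype=float))
        if self.V.shape != self.I.shape:
            raise ValueError("V and I must have identical shape")

    @property
    def n_sweeps(self) -> int:
        return self.V.shape[0]

    @property
    def duration(self) -> float:
        return self.V.shape[1] * self.dt

    @property
    def t(self) -> np.ndarray:
        return np.arange(self.V.shape[1]) * self.dt


@dataclass(frozen=True)
class ModelBank:
    """Bank of single-neuron parameter sets for one cell type."""

    cell_type: str
    models: tuple
    provenance: str = "synthetic"
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.models:
            raise ValueError("model bank must be nonempty")

    def __len__(self) -> int:
        return len(self.models)

    def __iter__(self):
        return iter(self.models)


# -- templates -------------------------------------------------------------

def _fc(weights) -> FilterCoeffs:
    return FilterCoeffs(weights=tuple(weights))


#: Template parameter sets per cell type.  Membrane R/C follow the measured
#: means; adaptation magnitudes are qualitative: 5-HT potent and protracted
#: (large eta and gamma over seconds), SOM weak, mPFC moderate.
CELL_TEMPLATES: Dict[str, GIFParamSet] = {
    "5-HT": AGIFParamSet(
        C=67.0, g_l=1.0 / 1.16, E_l=-70.0,
        eta=_fc([60.0, 36.0, 18.0, 7.5, 2.4, 0.45]),
        gamma=_fc([4.0, 2.0, 1.0, 0.5, 0.2, 0.05]),
        V_T_star=-45.0, DeltaV=1.0, V_reset=-48.0, T_ref=6.5,
        k_currents=PotassiumCurrentModel(g_A_bar=8.0, g_K_bar=1.6),
    ),
    "SOM": GIFParamSet(
        C=43.5, g_l=1.0 / 1.07, E_l=-65.0,
        eta=_fc([50.0, 25.0, 10.0, 3.8, 1.2, 0.2]),
        gamma=_fc([1.0, 0.5, 0.2, 0.0, 0.0, 0.0]),
        V_T_star=-47.0, DeltaV=1.0, V_reset=-60.0, T_ref=4.0,
    ),
    "mPFC": GIFParamSet(
        C=160.6, g_l=1.0 / 0.188, E_l=-70.0,
        eta=_fc([30.0, 15.0, 5.0, 1.0, 0.2, 0.0]),
        gamma=_fc([2.0, 1.0, 0.5, 0.2, 0.0, 0.0]),
        V_T_star=-48.0, DeltaV=1.0, V_reset=-55.0, T_ref=4.0,
    ),
}


@dataclass(frozen=True)
class HeterogeneitySpec:
    """Per-parameter jitter: CVs for positive (lognormal, mean-preserving)
    parameters and SDs (mV, normal) for potentials."""

    cv_R: float = 0.0  # jitter membrane resistance, then g_l = 1/R
    cv_C: float = 0.0
    sd_E_l: float = 0.0
    sd_V_T: float = 0.0
    cv_DeltaV: float = 0.0
    cv_adaptation: float = 0.0  # common lognormal factor on eta and gamma
    cv_g_A: float = 0.0

    @classmethod
    def none(cls) -> "HeterogeneitySpec":
        return cls()


#: Default heterogeneity per cell type.  R and C CVs follow the measured
#: mean +/- SD; SOM gain-related spreads (adaptation, threshold, slope
#: factor) are set larger than 5-HT, matching the reported heterogeneity.
CELL_HETEROGENEITY: Dict[str, HeterogeneitySpec] = {
    "5-HT": HeterogeneitySpec(cv_R=0.47, cv_C=0.255, sd_E_l=2.0, sd_V_T=2.0,
                              cv_DeltaV=0.2, cv_adaptation=0.3, cv_g_A=0.3),
    "SOM": HeterogeneitySpec(cv_R=0.54, cv_C=0.36, sd_E_l=4.0, sd_V_T=4.0,
                             cv_DeltaV=0.4, cv_adaptation=0.8, cv_g_A=0.0),
    "mPFC": HeterogeneitySpec(cv_R=0.69, cv_C=0.30, sd_E_l=2.0, sd_V_T=2.0,
                              cv_DeltaV=0.2, cv_adaptation=0.4, cv_g_A=0.0),
}


def cell_template(cell_type: str) -> GIFParamSet:
    try:
        return CELL_TEMPLATES[cell_type]
    except KeyError:
        raise KeyError(f"unknown cell type {cell_type!r}") from None


def _lognormal_factor(rng: np.random.Generator, cv: float) -> float:
    """Mean-1 lognormal multiplier with coefficient of variation ``cv``."""
    if cv <= 0:
        return 1.0
    s2 = np.log1p(cv * cv)
    return float(rng.lognormal(mean=-s2 / 2.0, sigma=np.sqrt(s2)))


def generate_bank(
    cell_type: str,
    n_models: int,
    heterogeneity: Optional[HeterogeneitySpec] = None,
    seed: int = 0,
    validate: bool = True,
) -> ModelBank:
    """Draw a bank of jittered parameter sets around the cell-type template.

    Positive parameters are jittered lognormally (mean-preserving);
    potentials normally.  Draws violating validity constraints
    (E_l < V_T*, positive conductances) are retried up to 100 times.
    With ``validate`` each model is probed with a short zero-input
    simulation; a failure raises.
    """
    template = cell_template(cell_type)
    if heterogeneity is None:
        heterogeneity = CELL_HETEROGENEITY[cell_type]
    het = heterogeneity
    rng = np.random.default_rng(seed)
    models: List[GIFParamSet] = []
    for _ in range(n_models):
        for attempt in range(100):
            R = (1.0 / template.g_l) * _lognormal_factor(rng, het.cv_R)
            C = template.C * _lognormal_factor(rng, het.cv_C)
            E_l = template.E_l + het.sd_E_l * rng.standard_normal()
            V_T = template.V_T_star + het.sd_V_T * rng.standard_normal()
            DV = template.DeltaV * _lognormal_factor(rng, het.cv_DeltaV)
            adapt = _lognormal_factor(rng, het.cv_adaptation)
            if E_l < V_T - 2.0 and R > 0 and C > 0:
                break
        else:
            raise RuntimeError("no valid parameter draw after 100 retries")
        fields = dict(
            C=C, g_l=1.0 / R, E_l=E_l,
            eta=template.eta.scaled(adapt), gamma=template.gamma.scaled(adapt),
            V_T_star=V_T, DeltaV=DV,
            V_reset=template.V_reset, T_ref=template.T_ref,
        )
        if isinstance(template, AGIFParamSet):
            kc = replace(template.k_currents,
                         g_A_bar=template.k_currents.g_A_bar
                         * _lognormal_factor(rng, het.cv_g_A))
            models.append(AGIFParamSet(k_currents=kc, **fields))
        else:
            models.append(GIFParamSet(**fields))

    if validate:
        probe = np.zeros(int(round(1000.0 / 0.1)))
        for m in models:
            simulate(m, probe, dt=0.1, seed=0)

    return ModelBank(cell_type=cell_type, models=tuple(models),
                     provenance="synthetic", seed=seed)


def generate_surrogate_recording(
    model: GIFParamSet,
    protocol: TrainValProtocol,
    obs_noise_sd: float = 0.0,
    seed: int = 0,
) -> Dict[str, Recording]:
    """Simulate a surrogate current-clamp experiment for one model.

    Returns {"train": Recording, "validation": Recording}: the training
    stimulus repeated ``protocol.n_train`` times and the validation
    stimulus ``protocol.n_val`` times, each sweep with an independent
    spiking realization (the stimulus itself is frozen), plus optional
    white Gaussian observation noise on V only.  Spike bins are marked
    with a +30 mV action-potential peak so that threshold-crossing spike
    detection behaves as on real recordings.
    """
    rng_seeds = np.random.SeedSequence(seed).generate_state(
        protocol.n_train + protocol.n_val) >> 1
    noise_rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))

    def _sweeps(stim: np.ndarray, n: int, seeds) -> Recording:
        V = np.empty((n, stim.size))
        for k in range(n):
            res = simulate(model, stim, dt=protocol.dt, seed=int(seeds[k]))
            V[k] = res.V
            spike_bins = np.asarray(np.rint(res.spikes / protocol.dt), dtype=int)
            V[k, spike_bins] = 30.0  # AP peak marker
            if obs_noise_sd > 0:
                V[k] += obs_noise_sd * noise_rng.standard_normal(stim.size)
        return Recording(V=V, I=np.tile(stim, (n, 1)), dt=protocol.dt,
                         cell_type=protocol.cell_type,
                         metadata={"seed": seed, "obs_noise_sd": obs_noise_sd,
                                   "ou": protocol.ou.__dict__.copy()})

    train = _sweeps(protocol.train, protocol.n_train, rng_seeds[:protocol.n_train])
    val = _sweeps(protocol.validation, protocol.n_val, rng_seeds[protocol.n_train:])
    return {"train": train, "validation": val}
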