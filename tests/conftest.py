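"""Shared fixtures: synthetic banks, surrogate recordings, fitted models.

Expensive artifacts (60 s surrogate recording, two-stage aGIF fit, FFI
network) are session-scoped so the fitting, metrics and acceptance tests
share one computation.
"""

import numpy as np
import pytest

from agifsim.fitting import fit_gif
from agifsim.network import NetworkModel
from agifsim.stimuli import training_validation_protocol
from agifsim.synth import CELL_TEMPLATES, generate_bank, generate_surrogate_recording


@pytest.fixture(scope="session")
def ht_template():
    return CELL_TEMPLATES["5-HT"]


@pytest.fixture(scope="session")
def surrogate_5ht(ht_template):
    """60 s training + 10x10 s validation surrogate from the 5-HT template."""
    proto = training_validation_protocol("5-HT", seed=42, n_val=10)
    recs = generate_surrogate_recording(ht_template, proto, obs_noise_sd=0.0, seed=7)
    return proto, recs


@pytest.fixture(scope="session")
def fitted_agif(surrogate_5ht):
    proto, recs = surrogate_5ht
    model, sub, thr = fit_gif(recs["train"], kind="aGIF")
    return model, sub, thr


@pytest.fixture(scope="session")
def som_bank():
    return generate_bank("SOM", 40, seed=1)


@pytest.fixture(scope="session")
def ht_bank():
    return generate_bank("5-HT", 40, seed=2)


@pytest.fixture(scope="session")
def ffi_net(som_bank, ht_bank):
    """Scaled-down FFI network: 60 SOM -> 100 5-HT with expected in-degree 8."""
    return NetworkModel.build(som_bank, ht_bank, n_som=60, n_ht=100,
                              p=8 / 60, seed=3)


@pytest.fixture(scope="session")
def no_ffi_net(ffi_net):
    return NetworkModel(som_models=ffi_net.som_models,
                        ht_models=ffi_net.ht_models,
                        W=np.zeros_like(ffi_net.W),
                        synapse=ffi_net.synapse)
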