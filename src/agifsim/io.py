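"""Serialization: model parameter JSON, recording HDF5, run manifests.

Conventions: units are mV, ms, pA, nS, pF everywhere; model JSON uses
canonical key order and a fixed float format so save/load round-trips are
byte-identical; HDF5 recordings follow the layout
``/cells/<id>/sweeps/<k>/{V, I}`` with attributes ``dt``, ``cell_type``.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict
from pathlib import Path
from typing import Dict, Optional, Union

import h5py
import numpy as np

from .kinetics import GatingParams, PotassiumCurrentModel
from .models import AGIFParamSet, FilterCoeffs, GIFParamSet, IGIFParamSet
from .synth import Recording

__all__ = [
    "model_to_dict",
    "model_from_dict",
    "save_model",
    "load_model",
    "save_recording",
    "load_recording",
    "write_manifest",
]

_FLOAT_FMT = "%.17g"  # lossless float64 round-trip


def _canonical(obj):
    if isinstance(obj, float):
        return float(_FLOAT_FMT % obj)
    if isinstance(obj, dict):
        return {k: _canonical(v) for k, v in sorted(obj.items())}
    if isinstance(obj, (list, tuple)):
        return [_canonical(v) for v in obj]
    return obj


def model_to_dict(model: GIFParamSet) -> Dict:
    d = asdict(model)
    if isinstance(model, IGIFParamSet):
        d["kind"] = "iGIF"
    elif isinstance(model, AGIFParamSet):
        d["kind"] = "aGIF"
    else:
        d["kind"] = "GIF"
    d["units"] = "mV, ms, pA, nS, pF"
    return _canonical(d)


def model_from_dict(d: Dict) -> GIFParamSet:
    d = dict(d)
    kind = d.pop("kind", "GIF")
    d.pop("units", None)
    d["eta"] = FilterCoeffs(weights=tuple(d["eta"]["weights"]),
                            timescales=tuple(d["eta"]["timescales"]))
    d["gamma"] = FilterCoeffs(weights=tuple(d["gamma"]["weights"]),
                              timescales=tuple(d["gamma"]["timescales"]))
    if kind == "aGIF":
        kc = d.pop("k_currents")
        gates = {g: GatingParams(**kc.pop(g)) for g in ("m_gate", "h_gate", "n_gate")}
        d["k_currents"] = PotassiumCurrentModel(**kc, **gates)
        return AGIFParamSet(**d)
    if kind == "iGIF":
        d["theta_steps"] = tuple(d["theta_steps"])
        d["bin_edges"] = tuple(d["bin_edges"])
        return IGIFParamSet(**d)
    if kind != "GIF":
        raise ValueError(f"unknown model kind {kind!r}")
    return GIFParamSet(**d)


def save_model(model: GIFParamSet, path: Union[str, Path]) -> None:
    Path(path).write_text(
        json.dumps(model_to_dict(model), indent=2, sort_keys=True) + "\n")


def load_model(path: Union[str, Path]) -> GIFParamSet:
    return model_from_dict(json.loads(Path(path).read_text()))


def save_recording(rec: Recording, path: Union[str, Path],
                   cell_id: str = "cell0") -> None:
    with h5py.File(path, "a") as f:
        grp = f.require_group(f"cells/{cell_id}")
        grp.attrs["dt"] = rec.dt
        grp.attrs["cell_type"] = rec.cell_type
        for key, val in rec.metadata.items():
            try:
                grp.attrs[f"meta_{key}"] = val
            except TypeError:
                grp.attrs[f"meta_{key}"] = json.dumps(val)
        sweeps = grp.require_group("sweeps")
        for k in range(rec.n_sweeps):
            sg = sweeps.require_group(str(k))
            for name, arr in (("V", rec.V[k]), ("I", rec.I[k])):
                if name in sg:
                    del sg[name]
                sg.create_dataset(name, data=arr, compression="gzip")


def load_recording(path: Union[str, Path], cell_id: str = "cell0") -> Recording:
    with h5py.File(path, "r") as f:
        grp = f[f"cells/{cell_id}"]
        dt = float(grp.attrs["dt"])
        cell_type = str(grp.attrs["cell_type"])
        keys = sorted(grp["sweeps"], key=int)
        V = np.stack([grp[f"sweeps/{k}/V"][:] for k in keys])
        I = np.stack([grp[f"sweeps/{k}/I"][:] for k in keys])
        meta = {k[5:]: grp.attrs[k] for k in grp.attrs if k.startswith("meta_")}
    return Recording(V=V, I=I, dt=dt, cell_type=cell_type, metadata=meta)


def write_manifest(path: Union[str, Path], stage: str, config: Dict,
                   seeds: Dict, inputs: Optional[Dict[str, Union[str, Path]]] = None) -> Dict:
    """Write a reproducibility manifest: config snapshot, seeds, version,
    input digests."""
    from . import __version__

    digests = {}
    for name, p in (inputs or {}).items():
        digests[name] = hashlib.sha256(Path(p).read_bytes()).hexdigest()
    manifest = {
        "stage": stage,
        "version": __version__,
        "config": _canonical(config),
        "seeds": _canonical(seeds),
        "input_digests": digests,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
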