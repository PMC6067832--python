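"""Persistence: HDF5 model snapshots, run manifests, and CSV table export.

Snapshots hold every mutable array (weights, thresholds, traces), the iteration
counter, the resolved config (as JSON) and the RNG state, and round-trip
bit-exactly: loading a snapshot and continuing training equals uninterrupted
training for the same seed stream.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .config import config_from_dict, config_to_dict
from .model import ModelState, build_model

__all__ = ["save_state", "load_state", "write_manifest", "write_training_log"]


def save_state(state: ModelState, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        f.attrs["config_json"] = json.dumps(config_to_dict(state.config))
        f.attrs["seed"] = state.seed
        f.attrs["iteration"] = state.iteration
        f.attrs["rng_state"] = json.dumps(state.rng.bit_generator.state)
        g = f.create_group("weights")
        g.create_dataset("afferent", data=state.afferent.w)
        g.create_dataset("lateral_exc", data=state.lateral_exc.w)
        g.create_dataset("lateral_inh", data=state.lateral_inh.w)
        f.create_dataset("theta", data=state.theta)
        f.create_dataset("ybar", data=state.ybar)
        f.attrs["perturbation_log"] = json.dumps(state.perturbation_log)
        f.attrs["training_log"] = json.dumps(state.log)


def load_state(path: str | Path) -> ModelState:
    """Rebuild a model state from a snapshot.

    The structural arrays (patch indices, masks, fixed kernels) are rebuilt
    from the stored config; the mutable arrays and RNG state are restored
    bit-exactly.
    """
    with h5py.File(path, "r") as f:
        cfg = config_from_dict(json.loads(f.attrs["config_json"]))
        state = build_model(cfg, seed=int(f.attrs["seed"]))
        state.afferent.w[...] = f["weights/afferent"][...]
        state.lateral_exc.w[...] = f["weights/lateral_exc"][...]
        state.lateral_inh.w[...] = f["weights/lateral_inh"][...]
        state.theta[...] = f["theta"][...]
        state.ybar[...] = f["ybar"][...]
        state.iteration = int(f.attrs["iteration"])
        rng_state = json.loads(f.attrs["rng_state"])
        state.rng.bit_generator.state = rng_state
        state.perturbation_log = json.loads(f.attrs["perturbation_log"])
        state.log = json.loads(f.attrs["training_log"])
    return state


def write_manifest(manifest: dict, path: str | Path) -> None:
    """Write a plain-text run manifest (JSON) with an output-file inventory."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    inventory = {}
    for p in sorted(path.parent.glob("*")):
        if p.is_file() and p != path:
            import hashlib

            inventory[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()[:16]
    manifest = dict(manifest, output_files=inventory)
    path.write_text(json.dumps(manifest, indent=2, default=_json_default) + "\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, tuple):
        return list(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_training_log(state: ModelState, path: str | Path) -> None:
    """Per-logpoint convergence audit CSV."""
    import pandas as pd

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(state.log).to_csv(path, index=False)
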