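"""Serialization: networks to .npz archives, traces to CSV, configs to YAML/JSON."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .network import LayeredNetwork, get_activation
from .pcn import RelaxationConfig, RelaxationResult

__all__ = [
    "save_network",
    "load_network",
    "save_config",
    "load_config",
    "relaxation_config_from_dict",
    "trace_to_csv",
]


def save_network(net: LayeredNetwork, path: str | Path) -> None:
    arrays = {f"w{l}": w for l, w in enumerate(net.weights)}
    if net.weight_masks is not None:
        arrays.update({f"mask{l}": m for l, m in enumerate(net.weight_masks)})
    np.savez(
        path,
        layer_sizes=np.asarray(net.layer_sizes),
        activation=np.asarray(net.activation.name),
        **arrays,
    )


def load_network(path: str | Path) -> LayeredNetwork:
    with np.load(path) as data:
        sizes = [int(n) for n in data["layer_sizes"]]
        weights = [data[f"w{l}"] for l in range(len(sizes) - 1)]
        masks = None
        if "mask0" in data:
            masks = [data[f"mask{l}"].astype(bool) for l in range(len(sizes) - 1)]
        act = get_activation(str(data["activation"]))
    return LayeredNetwork(sizes, weights, act, masks)


def save_config(config: dict, path: str | Path) -> None:
    path = Path(path)
    text = json.dumps(config, indent=2) if path.suffix == ".json" else yaml.safe_dump(config)
    path.write_text(text)


def load_config(path: str | Path) -> dict:
    path = Path(path)
    text = path.read_text()
    return json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)


def relaxation_config_from_dict(d: dict) -> RelaxationConfig:
    """Build a relaxation config from keys {gamma0, max_steps, adaptive}."""
    kwargs = {k: d[k] for k in ("gamma0", "max_steps", "adaptive") if k in d}
    return RelaxationConfig(**kwargs)


def trace_to_csv(result: RelaxationResult, path: str | Path) -> None:
    """Energy and step-size trace of one relaxation as tidy CSV."""
    n = len(result.energy_trace)
    gammas = list(result.gamma_trace) + [np.nan] * (n - len(result.gamma_trace))
    pd.DataFrame({"sweep": range(n), "energy": result.energy_trace, "gamma": gammas}).to_csv(
        path, index=False
    )
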