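"""MIL aggregators: uniform bag -> (logits, patch scores) contract."""

from __future__ import annotations

import dataclasses
import json
import re
from pathlib import Path

import numpy as np

from .accounting import count_flops, count_params, format_flops, format_params
from .archs import (
    ARCHS,
    MILModel,
    ModelConfig,
    ModelOutput,
    build_model,
)

__all__ = [
    "ARCHS",
    "MILModel",
    "ModelConfig",
    "ModelOutput",
    "build_model",
    "count_flops",
    "count_params",
    "format_flops",
    "format_params",
    "config_from_name",
    "registry_names",
    "save_model",
    "load_model",
]


def save_model(model: MILModel, path: str | Path) -> None:
    """Single-file checkpoint: parameter arrays plus the embedded config."""
    arrays = {f"p{i}": p.data for i, p in enumerate(model.parameters())}
    np.savez(path, config=json.dumps(dataclasses.asdict(model.cfg)), **arrays)


def load_model(path: str | Path) -> MILModel:
    """Rebuild a model from a checkpoint written by :func:`save_model`."""
    with np.load(path, allow_pickle=False) as f:
        cfg = ModelConfig(**json.loads(str(f["config"])))
        model = build_model(cfg)
        params = model.parameters()
        for i, p in enumerate(params):
            arr = f[f"p{i}"]
            if arr.shape != p.data.shape:
                raise ValueError(f"checkpoint parameter p{i} has shape {arr.shape}, "
                                 f"expected {p.data.shape}")
            p.data = arr.astype(p.data.dtype)
    return model

_ALIASES = {
    "mean_pool": "mean_pool",
    "max_pool": "max_pool",
    "mean_pool_ins": "mean_pool_ins",
    "max_pool_ins": "max_pool_ins",
    "abmil": "abmil",
    "clam": "clam_lite",
    "clam_lite": "clam_lite",
    "madmil": "madmil",
    "dtfd": "dtfd",
    "acmil": "acmil_lite",
    "acmil_lite": "acmil_lite",
}


def config_from_name(name: str, n_classes: int = 2, seed: int = 0, **overrides) -> ModelConfig:
    """Parse a registry name like ``abmil``, ``madmil/4`` or ``abmil-add``.

    A ``/k`` suffix sets the head count of multi-head architectures; an
    ``-add`` suffix selects the additive reformulation.
    """
    key = name.strip().lower().replace("-", "_")
    additive = False
    if key.endswith("_add"):
        additive, key = True, key[:-4]
    heads = None
    m = re.fullmatch(r"([a-z_]+)/(\d+)", key)
    if m:
        key, heads = m.group(1), int(m.group(2))
    if key not in _ALIASES:
        raise KeyError(f"unknown model name {name!r}")
    kwargs = dict(arch=_ALIASES[key], additive=additive, n_classes=n_classes, seed=seed)
    if heads is not None:
        kwargs["heads"] = heads
    kwargs.update(overrides)
    return ModelConfig(**kwargs)


def registry_names() -> list[str]:
    """Canonical names of the benchmark model family."""
    return [
        "mean_pool", "max_pool", "mean_pool_ins", "max_pool_ins",
        "abmil", "abmil-add", "clam", "clam-add",
        "madmil/2", "acmil/2", "acmil/2-add", "dtfd",
    ]
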