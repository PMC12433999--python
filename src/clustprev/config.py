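"""YAML sidecar configuration for populations, models and pipelines."""
from __future__ import annotations

import dataclasses
from pathlib import Path

import yaml

from .attrition import MARModel
from .experiment import ExperimentGrid
from .glmm import ModelSpec
from .sknn import SknnConfig
from .synthetic import PopulationConfig

_SECTIONS = {
    "population": PopulationConfig,
    "model": ModelSpec,
    "mar": MARModel,
    "sknn": SknnConfig,
    "grid": ExperimentGrid,
}


def _coerce(cls, payload: dict):
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(payload) - fields
    if unknown:
        raise ValueError(f"unknown keys for {cls.__name__}: {sorted(unknown)}")
    kwargs = dict(payload)
    # tuples round-trip as YAML lists
    for f in dataclasses.fields(cls):
        if f.name in kwargs and isinstance(kwargs[f.name], list):
            kwargs[f.name] = tuple(kwargs[f.name])
    if cls is ExperimentGrid and "sknn" in kwargs and isinstance(kwargs["sknn"], dict):
        kwargs["sknn"] = _coerce(SknnConfig, kwargs["sknn"])
    return cls(**kwargs)


def load_config(path: str | Path) -> dict:
    """Load a nested key-value config file; returns dataclasses per section.

    Recognised top-level sections: population, model, mar, sknn, grid.
    """
    payload = yaml.safe_load(Path(path).read_text()) or {}
    out = {}
    for section, content in payload.items():
        if section not in _SECTIONS:
            raise ValueError(f"unknown config section {section!r}")
        out[section] = _coerce(_SECTIONS[section], content or {})
    return out


def _plain(value):
    """Recursively convert tuples and numpy scalars into plain YAML types."""
    if isinstance(value, (tuple, list)):
        return [_plain(v) for v in value]
    if isinstance(value, dict):
        return {k: _plain(v) for k, v in value.items()}
    if hasattr(value, "item"):  # numpy scalar
        return value.item()
    return value


def dump_config(objects: dict, path: str | Path) -> None:
    """Write dataclass sections back to a YAML file."""
    payload = {}
    for section, obj in objects.items():
        if section not in _SECTIONS:
            raise ValueError(f"unknown config section {section!r}")
        payload[section] = _plain(dataclasses.asdict(obj))
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))
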