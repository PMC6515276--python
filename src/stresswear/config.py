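"""Run configuration: YAML loading with strict key validation, defaults,
round-trip serialisation and master-seed fan-out."""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field, fields
from typing import Optional

import yaml

from .eda import EdaArtifactConfig
from .fusion import AggregationConfig
from .hr import RRCleanConfig
from .ml import ClassifierSpec
from .synthetic import ClassParams, SimConfig

__all__ = ["RunConfig", "load_config", "save_config", "derive_seed"]


def derive_seed(master: int, label: str) -> int:
    """Deterministic per-module seed derived from the master seed and a
    stage label; always below 2**31."""
    h = hashlib.sha256(f"{master}:{label}".encode()).digest()
    return int.from_bytes(h[:4], "little") % (2 ** 31)


@dataclass
class RunConfig:
    """Top-level configuration wiring every stage of the pipeline."""

    out_dir: str = "stresswear_out"
    seed: int = 0
    log_level: str = "INFO"
    n_subjects: int = 21
    sessions_per_subject: int = 3
    sim: SimConfig = field(default_factory=SimConfig)
    rr_clean: RRCleanConfig = field(default_factory=RRCleanConfig)
    eda_artifacts: EdaArtifactConfig = field(default_factory=EdaArtifactConfig)
    aggregation: AggregationConfig = field(default_factory=AggregationConfig)
    classifiers: tuple = (ClassifierSpec("rf100"),)


def _build(cls, data: dict, path: str):
    """Instantiate a (nested) dataclass, rejecting unknown keys."""
    known = {f.name: f for f in fields(cls)}
    unknown = set(data) - set(known)
    if unknown:
        raise ValueError(f"unknown config key(s) {sorted(unknown)} under '{path}'")
    kwargs = {}
    for name, value in data.items():
        f = known[name]
        if dataclasses.is_dataclass(f.type) and isinstance(value, dict):
            kwargs[name] = _build(f.type, value, f"{path}.{name}")
        elif name == "sim" and isinstance(value, dict):
            kwargs[name] = _build(SimConfig, value, f"{path}.{name}")
        elif name == "classes" and isinstance(value, dict):
            kwargs[name] = {
                k: _build(ClassParams, v, f"{path}.classes.{k}") for k, v in value.items()
            }
        elif name == "classifiers":
            kwargs[name] = tuple(
                _build(ClassifierSpec, v, f"{path}.classifiers") if isinstance(v, dict)
                else ClassifierSpec(kind=v)
                for v in value
            )
        elif name in ("modality_set", "gravity") and isinstance(value, list):
            kwargs[name] = tuple(value)
        else:
            kwargs[name] = value
    return cls(**kwargs)


_NESTED = {
    "sim": SimConfig,
    "rr_clean": RRCleanConfig,
    "eda_artifacts": EdaArtifactConfig,
    "aggregation": AggregationConfig,
}


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration; an empty file yields all
    defaults, unknown keys raise with the offending key named."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError("config root must be a mapping")
    known = {f.name for f in fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config key(s) {sorted(unknown)}")
    kwargs = {}
    for name, value in data.items():
        if name in _NESTED and isinstance(value, dict):
            kwargs[name] = _build(_NESTED[name], value, name)
        elif name == "classifiers":
            kwargs[name] = tuple(
                _build(ClassifierSpec, v, "classifiers") if isinstance(v, dict)
                else ClassifierSpec(kind=v)
                for v in value
            )
        else:
            kwargs[name] = value
    return RunConfig(**kwargs)


def _to_dict(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_dict(getattr(obj, f.name)) for f in fields(obj)}
    if isinstance(obj, dict):
        return {k: _to_dict(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_dict(v) for v in obj]
    return obj


def save_config(cfg: RunConfig, path) -> None:
    data = _to_dict(cfg)
    # the pluggable classifier callable is not serialisable; drop if unset
    if data["eda_artifacts"].get("classifier") is None:
        data["eda_artifacts"].pop("classifier")
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)
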