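"""YAML run configuration and master-seed management.

A single YAML file carries four sections — ``lif``, ``train``,
``synth`` and ``experiment`` — validated against their owning types at
load time, plus a ``master_seed``.  One master seed deterministically
derives every substream (data synthesis, weight init, epoch shuffling,
protocol splits) through named seed-sequence children, so one integer
reproduces an entire experiment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, fields, asdict
from typing import Union
import os

import numpy as np
import yaml

from .lif import LIFParams
from .synth import SynthConfig
from .tempotron import TrainConfig

__all__ = ["ExperimentConfig", "RunConfig", "load_config", "dump_config", "derive_seed"]

# fixed role table: the substream each component draws its seed from
_SEED_ROLES = {"synth": 0, "train": 1, "split": 2, "cv": 3}


def derive_seed(master_seed: int, role: str) -> int:
    """Deterministic sub-seed (< 2**31) for a named randomness role."""
    if role not in _SEED_ROLES:
        raise ValueError(f"unknown seed role {role!r}; known: {sorted(_SEED_ROLES)}")
    ss = np.random.SeedSequence([int(master_seed), _SEED_ROLES[role]])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass(frozen=True)
class ExperimentConfig:
    """Protocol parameters: repetitions and split sizes."""

    n_reps: int = 100
    train_per_class: int = 16
    decoder: str = "tempotron-vr"
    use_cv: bool = False

    def __post_init__(self) -> None:
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if self.train_per_class < 1:
            raise ValueError("train_per_class must be >= 1")


_SECTIONS = {
    "lif": LIFParams,
    "train": TrainConfig,
    "synth": SynthConfig,
    "experiment": ExperimentConfig,
}

# YAML spelling -> dataclass field (lambda is a Python keyword)
_ALIASES = {"train": {"lambda": "lam"}}


@dataclass(frozen=True)
class RunConfig:
    lif: LIFParams = field(default_factory=LIFParams)
    train: TrainConfig = field(default_factory=TrainConfig)
    synth: SynthConfig = field(default_factory=SynthConfig)
    experiment: ExperimentConfig = field(default_factory=ExperimentConfig)
    master_seed: int = 0


def _build_section(name: str, cls, payload: dict):
    known = {f.name for f in fields(cls) if f.name != "v0"}
    aliases = _ALIASES.get(name, {})
    kwargs = {}
    for key, value in payload.items():
        target = aliases.get(key, key)
        if target not in known:
            warnings.warn(f"unknown config key {name}.{key}", stacklevel=3)
            continue
        kwargs[target] = value
    try:
        return cls(**kwargs)
    except (ValueError, TypeError) as e:
        # name the offending key path where we can infer it
        for key in kwargs:
            if key in str(e):
                raise ValueError(f"{name}.{key}: {e}") from None
        raise ValueError(f"{name}: {e}") from None


def load_config(path: Union[str, os.PathLike, None] = None) -> RunConfig:
    """Load a YAML run config; absent fields take their defaults."""
    payload = {}
    if path is not None:
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
    if not isinstance(payload, dict):
        raise ValueError("config root must be a mapping")
    sections = {}
    for name, cls in _SECTIONS.items():
        raw = payload.pop(name, {}) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"{name}: must be a mapping")
        sections[name] = _build_section(name, cls, raw)
    master_seed = payload.pop("master_seed", 0)
    for key in payload:
        warnings.warn(f"unknown config key {key}", stacklevel=2)
    return RunConfig(master_seed=int(master_seed), **sections)


def dump_config(config: RunConfig, path: Union[str, os.PathLike, None] = None) -> str:
    """Serialize a run config back to YAML (derived fields dropped)."""
    doc = {
        name: {
            k: v
            for k, v in asdict(getattr(config, name)).items()
            if k != "v0"
        }
        for name in _SECTIONS
    }
    doc["master_seed"] = config.master_seed
    text = yaml.safe_dump(doc, sort_keys=True)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text
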