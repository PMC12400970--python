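"""Run configuration: nested YAML/JSON schema with strict key validation.

Every sub-seed is derived deterministically from ``master_seed``; the
resolved configuration's hash is embedded in outputs for provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .experiments import SCALE_PROFILES
from .nn.network import ModelConfig, TrainConfig
from .preprocess import PreprocessConfig


@dataclass(frozen=True)
class SimulateSection:
    scenario: str = "task"
    n_subjects: int | None = None
    trials_per_task: int | None = None
    n_colors: int | None = None
    behavioral_accuracy: float = 0.93
    artifact_rate: float = 0.0
    remap: bool = False


@dataclass(frozen=True)
class StatsSection:
    alpha: float = 0.05
    n_bootstrap: int | None = None


@dataclass(frozen=True)
class RunConfig:
    master_seed: int = 0
    scale_profile: str = "desk"
    simulate: SimulateSection = field(default_factory=SimulateSection)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    model: dict = field(default_factory=dict)  # overrides on the profile's ModelConfig
    train: dict = field(default_factory=dict)  # overrides on the profile's TrainConfig
    stats: StatsSection = field(default_factory=StatsSection)

    def __post_init__(self) -> None:
        if self.scale_profile not in SCALE_PROFILES:
            raise ValueError(
                f"unknown scale_profile {self.scale_profile!r}; "
                f"choose from {sorted(SCALE_PROFILES)}")
        for key in self.model:
            if key not in ModelConfig.__dataclass_fields__:
                raise ValueError(f"unknown model key {key!r}")
        for key in self.train:
            if key not in TrainConfig.__dataclass_fields__:
                raise ValueError(f"unknown train key {key!r}")

    def resolved_model_config(self) -> ModelConfig:
        base = SCALE_PROFILES[self.scale_profile].model_config
        return dataclasses.replace(base, **self.model)

    def resolved_train_config(self) -> TrainConfig:
        base = SCALE_PROFILES[self.scale_profile].train_config
        return dataclasses.replace(base, **self.train)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @property
    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _build_section(cls, data: dict, path: str):
    fields = cls.__dataclass_fields__
    unknown = set(data) - set(fields)
    if unknown:
        raise ValueError(f"unknown key(s) {sorted(unknown)} in section {path!r}")
    kwargs = {}
    for key, val in data.items():
        if isinstance(val, list):
            val = tuple(val)
        kwargs[key] = val
    try:
        return cls(**kwargs)
    except TypeError as exc:
        raise ValueError(f"type error in section {path!r}: {exc}") from None


def load_config(path) -> RunConfig:
    """Load + validate a YAML/JSON run configuration; defaults filled in,
    unknown keys rejected with the offending key named."""
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ValueError("config root must be a mapping")
    sections = {
        "simulate": SimulateSection,
        "preprocess": PreprocessConfig,
        "stats": StatsSection,
    }
    top_fields = set(RunConfig.__dataclass_fields__)
    unknown = set(data) - top_fields
    if unknown:
        raise ValueError(f"unknown top-level key(s): {sorted(unknown)}")
    kwargs: dict = {}
    for key, val in data.items():
        if key in sections:
            kwargs[key] = _build_section(sections[key], val or {}, key)
        elif key in ("model", "train"):
            kwargs[key] = dict(val or {})
        else:
            kwargs[key] = val
    return RunConfig(**kwargs)
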