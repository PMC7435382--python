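"""Run configuration: every tunable default of the pipeline in one
validated document, loadable from YAML.  Unknown keys are rejected so a
typo cannot silently fall back to a default.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .conditioning import ConditioningConfig

__all__ = ["RunConfig", "MlpConfig", "SimulationConfig"]


@dataclass(frozen=True)
class MlpConfig:
    hidden_units: int = 7
    patience: int = 6
    max_iter: int = 1000
    lambda0: float = 1e-3
    init_scale: float = 0.5


@dataclass(frozen=True)
class SimulationConfig:
    n_subjects: int = 3
    sensor: str = "gradeA"  # gradeA | gradeB | ideal
    n_maneuvers: int = 10
    tidal_cycles: int = 5
    fvc_duration: float = 6.0
    rise_time: float = 0.1
    tail_s: float = 1.0
    reference_rate: float = 50.0
    reference_noise_sd: float = 0.02
    reference_offset: float = 0.01


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    model: str = "root4"
    robust: bool = False
    scheme: str = "inclusive"
    n_folds: int = 5
    range_scope: str = "global"
    conditioning: ConditioningConfig = field(default_factory=ConditioningConfig)
    mlp: MlpConfig = field(default_factory=MlpConfig)
    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    @classmethod
    def from_dict(cls, doc: dict) -> "RunConfig":
        doc = dict(doc or {})
        kwargs = {}
        for name, sub in (
            ("conditioning", ConditioningConfig),
            ("mlp", MlpConfig),
            ("simulation", SimulationConfig),
        ):
            if name in doc:
                section = doc.pop(name)
                _check_keys(section, sub, name)
                kwargs[name] = sub(**section)
        _check_keys(doc, cls, "run")
        return cls(**doc, **kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def resolved(self) -> dict:
        """Fully-resolved configuration for run logs."""
        return dataclasses.asdict(self)


def _check_keys(section: dict, cls, name: str) -> None:
    known = {f.name for f in dataclasses.fields(cls)} - {"conditioning", "mlp", "simulation"}
    unknown = set(section) - known
    if unknown:
        raise ValueError(f"unknown {name} config keys: {sorted(unknown)}")
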