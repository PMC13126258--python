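"""Configuration loading, validation and run manifests.

A single JSON document configures a run: simulation geometry/horizon,
learnable parameters, and an optional therapy schedule. Unknown keys are
rejected with the offending field path; defaults are filled for anything
omitted, so an empty document is a valid all-defaults configuration. Every
run can be summarized by a manifest (config hash + seed list + outputs)
from which it is reproducible.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Dict, List, Optional

from pydantic import BaseModel, ConfigDict, ValidationError

from . import __version__ as _pkg_version
from .engine import SimulationConfig
from .params import LearnableParameterSet
from .therapy import TherapySchedule

__all__ = ["FullConfig", "RunManifest", "ConfigError", "load_config", "config_hash"]


class ConfigError(ValueError):
    pass


class FullConfig(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)

    simulation: SimulationConfig = SimulationConfig()
    parameters: LearnableParameterSet = LearnableParameterSet()
    therapy: Optional[TherapySchedule] = None

    def simulation_config(self) -> SimulationConfig:
        return self.simulation.model_copy(update={"params": self.parameters,
                                                  "therapy": self.therapy})


def _format_validation_error(exc: ValidationError) -> str:
    parts = []
    for err in exc.errors():
        loc = ".".join(str(p) for p in err["loc"]) or "<root>"
        parts.append(f"{loc}: {err['msg']}")
    return "; ".join(parts)


def load_config(path: str | Path | None) -> FullConfig:
    """Load and validate a JSON config file; ``None`` or an empty file gives
    the all-defaults configuration."""
    if path is None:
        return FullConfig()
    text = Path(path).read_text().strip()
    if not text:
        return FullConfig()
    try:
        data = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ConfigError(f"invalid JSON in {path}: {exc}") from exc
    try:
        return FullConfig(**data)
    except ValidationError as exc:
        raise ConfigError(_format_validation_error(exc)) from exc
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc


def config_hash(config: FullConfig) -> str:
    """Stable hash of the fully-resolved configuration."""
    blob = json.dumps(config.model_dump(), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


class RunManifest(BaseModel):
    model_config = ConfigDict(extra="forbid")

    config_hash: str
    seeds: List[int]
    version: str = _pkg_version
    outputs: List[str] = []

    @classmethod
    def for_run(cls, config: FullConfig, seeds: List[int],
                outputs: List[str]) -> "RunManifest":
        return cls(config_hash=config_hash(config), seeds=list(seeds),
                   outputs=sorted(outputs))

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.model_dump(), indent=1))
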