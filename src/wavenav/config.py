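"""Simulation configuration: defaults, validation, JSON (de)serialization.

A :class:`SimulationConfig` gathers everything a run needs — grid, maze,
endpoints, the three parameter groups, heterogeneity and seed — and
round-trips losslessly through JSON.  Defaults reproduce the reference
parameter tables (41x41 grid, RS/FS neurons, s_ee_max = 50, I_dc = 25,
sigma = 0.03, T = 0.05, J = 12, tau = 0.8, R = 12 ms).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np

from .attractor import AttractorConfig
from .coupling import PlannerConfig
from .errors import ConfigurationError
from .topology import GridManifold, build_manifold, make_maze, read_mask
from .wave_layer import HeterogeneityConfig, SynapseConfig

__all__ = ["SimulationConfig", "load_config", "save_config"]


@dataclass(frozen=True)
class SimulationConfig:
    nx: int = 41
    ny: int = 41
    maze: str = "open"  # one of MAZE_KINDS, or "file"
    mask_path: str | None = None  # used when maze == "file"
    start: tuple[int, int] = (5, 5)
    target: tuple[int, int] = (35, 35)
    synapse: SynapseConfig = field(default_factory=SynapseConfig)
    attractor: AttractorConfig = field(default_factory=AttractorConfig)
    planner: PlannerConfig = field(default_factory=PlannerConfig)
    heterogeneity: HeterogeneityConfig = field(default_factory=HeterogeneityConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.attractor.nx, self.attractor.ny) != (self.nx, self.ny):
            object.__setattr__(
                self,
                "attractor",
                dataclasses.replace(self.attractor, nx=self.nx, ny=self.ny),
            )
        for name, (x, y) in (("start", self.start), ("target", self.target)):
            if not (0 <= x < self.nx and 0 <= y < self.ny):
                raise ConfigurationError(f"{name} {x, y} outside the grid")

    # -- derived objects -------------------------------------------------

    def manifold(self) -> GridManifold:
        if self.maze == "file":
            if not self.mask_path:
                raise ConfigurationError("maze='file' requires mask_path")
            mask = read_mask(self.mask_path)
            if mask.shape != (self.ny, self.nx):
                raise ConfigurationError(
                    f"mask file shape {mask.shape} does not match grid"
                )
        else:
            mask = make_maze(
                self.maze, self.nx, self.ny,
                start=self.start, target=self.target,
                interaction_range=self.synapse.d_e,
            )
        return build_manifold(self.nx, self.ny, mask)

    def start_id(self) -> int:
        return self.start[1] * self.nx + self.start[0]

    def target_id(self) -> int:
        return self.target[1] * self.nx + self.target[0]

    # -- serialization ---------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        return {
            "nx": self.nx,
            "ny": self.ny,
            "maze": self.maze,
            "mask_path": self.mask_path,
            "start": list(self.start),
            "target": list(self.target),
            "synapse": dataclasses.asdict(self.synapse),
            "attractor": dataclasses.asdict(self.attractor),
            "planner": dataclasses.asdict(self.planner),
            "heterogeneity": dataclasses.asdict(self.heterogeneity),
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "SimulationConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        kwargs: dict[str, Any] = {}
        for key, value in data.items():
            if key in ("start", "target"):
                kwargs[key] = tuple(int(v) for v in value)
            elif key == "synapse":
                kwargs[key] = _sub(SynapseConfig, value, key)
            elif key == "attractor":
                kwargs[key] = _sub(AttractorConfig, value, key)
            elif key == "planner":
                kwargs[key] = _sub(PlannerConfig, value, key)
            elif key == "heterogeneity":
                kwargs[key] = _sub(HeterogeneityConfig, value, key)
            else:
                kwargs[key] = value
        return cls(**kwargs)


def _sub(cls: type, data: dict[str, Any], path: str) -> Any:
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ConfigurationError(
            f"unknown config keys under '{path}': {sorted(unknown)}"
        )
    try:
        return cls(**data)
    except ConfigurationError as exc:
        raise ConfigurationError(f"in '{path}': {exc}") from exc


def load_config(path: str | Path) -> SimulationConfig:
    """Parse and validate a JSON config file; absent fields get defaults."""
    text = Path(path).read_text()
    data = json.loads(text) if text.strip() else {}
    if not isinstance(data, dict):
        raise ConfigurationError(f"{path}: top level must be a JSON object")
    return SimulationConfig.from_dict(data)


def save_config(cfg: SimulationConfig, path: str | Path) -> None:
    Path(path).write_text(json.dumps(cfg.to_dict(), indent=2) + "\n")
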