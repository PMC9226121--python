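"""Named experiment setups matching the study's figure configurations.

``open``           : fully open 41x41 grid, diagonal start/target.
``s_maze``         : S-shaped corridor forced by two interleaved walls.
``blocks``         : rectangular obstacle field.
``fine_structure`` : dense comb labyrinth.
``heterogeneous``  : blocks maze with randomized neuron phenotypes and
                     +-10 % synaptic jitter.
"""

from __future__ import annotations

import dataclasses

from .config import SimulationConfig
from .errors import ConfigurationError
from .wave_layer import HeterogeneityConfig

__all__ = ["PRESETS", "get_preset"]


def _base(maze: str, start, target) -> SimulationConfig:
    return SimulationConfig(maze=maze, start=start, target=target)


PRESETS: dict[str, SimulationConfig] = {
    "open": _base("open", (5, 5), (35, 35)),
    "s_maze": _base("s_maze", (2, 2), (38, 38)),
    "blocks": _base("blocks", (2, 2), (38, 38)),
    "fine_structure": _base("fine_structure", (2, 2), (38, 38)),
    "heterogeneous": dataclasses.replace(
        _base("blocks", (2, 2), (38, 38)),
        heterogeneity=HeterogeneityConfig(enabled=True),
    ),
}


def get_preset(name: str, seed: int | None = None) -> SimulationConfig:
    if name not in PRESETS:
        raise ConfigurationError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        )
    cfg = PRESETS[name]
    if seed is not None:
        cfg = dataclasses.replace(cfg, seed=int(seed))
    return cfg
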