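"""Shared fixtures.

Expensive simulations (a full 300 ms wave sweep, the four planning
presets) are session-scoped so every test module can interrogate the same
run instead of recomputing it.
"""

from __future__ import annotations

import numpy as np
import pytest

import wavenav as wn
from wavenav.presets import get_preset


@pytest.fixture(scope="session")
def open41():
    return wn.build_manifold(41, 41)


@pytest.fixture(scope="session")
def wave300(open41):
    """Open 41x41 grid, center permanently stimulated, 300 ms."""
    center = open41.node_id(20, 20)
    layer = wn.WaveLayer(open41, stim_nodes=(center,), record_raster=True)
    layer.run(300)
    return layer, center


@pytest.fixture(scope="session")
def relaxed_bump(open41):
    cfg = wn.AttractorConfig()
    state = wn.initialize_bump(open41.node_id(20, 20), cfg, open41)
    return state, cfg


@pytest.fixture(scope="session")
def preset_runs():
    """Planner runs for the four homogeneous presets, keyed by name."""
    out = {}
    for name in ("open", "blocks", "s_maze", "fine_structure"):
        cfg = get_preset(name)
        manifold = cfg.manifold()
        run = wn.run_planner(
            manifold,
            cfg.start_id(),
            cfg.target_id(),
            syn=cfg.synapse,
            attractor=cfg.attractor,
            planner=cfg.planner,
        )
        out[name] = (cfg, manifold, run)
    return out
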