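"""End-to-end acceptance measurements.

Recomputes, from scratch, the quantities the model is validated against:
wave speed and BFS-rank agreement on the open grid, the relaxed bump
diameter, the four planning presets (arrival, efficiency, ordering), and
the heterogeneous robustness suite.  Used by ``wavenav validate`` and by
``scripts/acceptance.py``.
"""

from __future__ import annotations

from typing import Callable

import numpy as np

from .analysis import wave_speed
from .attractor import AttractorConfig, bump_diameter, initialize_bump
from .coupling import Planner, path_efficiency
from .presets import get_preset
from .topology import bfs_distances, build_manifold, connectivity_graph
from .wave_layer import WaveLayer

__all__ = ["run_acceptance"]


def _echo_default(msg: str) -> None:
    pass


def run_acceptance(
    seed: int = 1,
    quick: bool = False,
    echo: Callable[[str], None] = _echo_default,
) -> dict[str, dict[str, float | int]]:
    """Compute all acceptance quantities; returns {name: {value, n}}.

    ``seed`` drives the heterogeneous randomizations (the homogeneous
    measurements are fully deterministic).  ``quick`` skips the planning
    and heterogeneous suites.
    """
    results: dict[str, dict[str, float | int]] = {}

    # --- wave layer: speed and BFS equivalence on the open grid --------
    echo("wave layer: open 41x41, center stimulated, 300 ms ...")
    manifold = build_manifold(41, 41)
    center = manifold.node_id(20, 20)
    layer = WaveLayer(manifold, stim_nodes=(center,))
    n_free = manifold.n_free
    peak_frac = 0.0
    for _ in range(300):
        layer.step()
        peak_frac = max(
            peak_frac, np.count_nonzero(layer.spiked_exc) / n_free
        )
    speed, rho = wave_speed(layer, center)
    results["wave_speed_cells_per_ms"] = {"value": round(speed, 3), "n": n_free}
    results["wave_bfs_spearman"] = {"value": round(rho, 4), "n": n_free}
    results["wave_peak_spike_fraction"] = {
        "value": round(peak_frac, 4), "n": n_free,
    }

    # --- resting stability --------------------------------------------
    echo("wave layer: unstimulated rest, 500 ms ...")
    silent = WaveLayer(manifold)
    spikes = 0
    for _ in range(500):
        silent.step()
        spikes += int(np.count_nonzero(silent.spiked_exc))
        spikes += int(np.count_nonzero(silent.spiked_inh))
    results["resting_spike_count_500ms"] = {"value": spikes, "n": n_free}

    # --- attractor bump ------------------------------------------------
    echo("attractor: relaxing the bump ...")
    acfg = AttractorConfig()
    bump = initialize_bump(center, acfg, manifold)
    results["bump_diameter_cells"] = {
        "value": bump_diameter(bump, acfg, 0.1), "n": acfg.nx * acfg.ny,
    }

    if quick:
        return results

    # --- planning presets ----------------------------------------------
    arrivals = 0
    hops_by_preset: dict[str, int] = {}
    time_by_preset: dict[str, float] = {}
    for name in ("open", "blocks", "s_maze", "fine_structure"):
        echo(f"planning preset {name} ...")
        cfg = get_preset(name)
        m = cfg.manifold()
        planner = Planner(
            m, cfg.start_id(), cfg.target_id(),
            syn=cfg.synapse, attractor=cfg.attractor, planner=cfg.planner,
        )
        run = planner.run()
        graph = connectivity_graph(m, cfg.synapse.d_e)
        hops_by_preset[name] = bfs_distances(graph, run.start)[run.target]
        if run.status == "arrived":
            arrivals += 1
            time_by_preset[name] = run.arrival_time_ms
            eff = path_efficiency(run, m, cfg.synapse.d_e)
            results[f"{name}_path_efficiency"] = {
                "value": round(eff, 3), "n": hops_by_preset[name],
            }
            results[f"{name}_arrival_time_ms"] = {
                "value": run.arrival_time_ms, "n": hops_by_preset[name],
            }
    results["planning_presets_arrived"] = {"value": arrivals, "n": 4}
    if len(time_by_preset) == 4:
        order_match = sorted(hops_by_preset, key=hops_by_preset.get) == sorted(
            time_by_preset, key=time_by_preset.get
        )
        results["arrival_order_matches_path_length_order"] = {
            "value": int(order_match), "n": 4,
        }

    # --- heterogeneous robustness --------------------------------------
    cfg = get_preset("heterogeneous")
    m = cfg.manifold()
    het_arrivals = 0
    coverage = []
    for i in range(10):
        run_seed = seed * 10 + i
        echo(f"heterogeneous run, seed {run_seed} ...")
        planner = Planner(
            m, cfg.start_id(), cfg.target_id(),
            syn=cfg.synapse, attractor=cfg.attractor, planner=cfg.planner,
            heterogeneity=cfg.heterogeneity,
            rng=np.random.default_rng(run_seed),
        )
        run = planner.run()
        het_arrivals += run.status == "arrived"
        reached = ~np.isnan(planner.wave.first_spike_exc)
        coverage.append(reached[~m.blocked_flat].mean())
    results["heterogeneous_arrivals_of_10"] = {"value": het_arrivals, "n": 10}
    results["heterogeneous_wave_coverage"] = {
        "value": round(float(np.min(coverage)), 4), "n": m.n_free,
    }
    return results
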