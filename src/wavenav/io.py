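"""Run artifact writers: trajectory/raster CSV and JSON summary.

All outputs are deterministic functions of (config, seed): fixed file
names, comma-separated CSV with a header row and LF line endings, and a
summary that embeds the full effective configuration.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .attractor import AttractorConfig, AttractorState
from .config import SimulationConfig
from .coupling import PlannerRun, path_efficiency
from .topology import GridManifold

__all__ = ["write_run_outputs", "write_activation_snapshot"]


def write_activation_snapshot(
    state: AttractorState,
    cfg: AttractorConfig,
    path: str | Path,
) -> None:
    """Write the nonzero activation field as (t_ms, node_x, node_y, A) CSV."""
    import numpy as np

    ids = np.flatnonzero(state.A > 0)
    pd.DataFrame(
        {
            "t_ms": state.t,
            "node_x": ids % cfg.nx,
            "node_y": ids // cfg.nx,
            "A": state.A[ids],
        }
    ).to_csv(path, index=False, lineterminator="\n")


def write_run_outputs(
    run: PlannerRun,
    manifold: GridManifold,
    cfg: SimulationConfig,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write trajectory.csv, raster.csv and summary.json into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    rows = []
    for t, node in run.trajectory:
        x, y = manifold.node_xy(node)
        rows.append({"t_ms": t, "center_x": x, "center_y": y})
    traj_path = out / "trajectory.csv"
    pd.DataFrame(rows, columns=["t_ms", "center_x", "center_y"]).to_csv(
        traj_path, index=False, lineterminator="\n"
    )
    paths["trajectory"] = traj_path

    raster_path = out / "raster.csv"
    pd.DataFrame(
        run.raster, columns=["t_ms", "population", "node_x", "node_y"]
    ).to_csv(raster_path, index=False, lineterminator="\n")
    paths["raster"] = raster_path

    from .coupling import bfs_distances, connectivity_graph  # local, cheap

    graph = connectivity_graph(manifold, cfg.synapse.d_e)
    bfs_hops = bfs_distances(graph, run.start).get(run.target)
    summary = {
        "status": run.status,
        "path_hops": run.path_hops,
        "bfs_hops": bfs_hops,
        "efficiency": (
            round(path_efficiency(run, manifold, cfg.synapse.d_e), 4)
            if run.status == "arrived" and bfs_hops
            else None
        ),
        "arrival_time_ms": run.arrival_time_ms,
        "n_direction_updates": run.n_direction_updates,
        "seed": run.seed,
        "config": cfg.to_dict(),
    }
    summary_path = out / "summary.json"
    summary_path.write_text(json.dumps(summary, indent=2) + "\n")
    paths["summary"] = summary_path
    return paths
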