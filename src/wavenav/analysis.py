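"""Measurement helpers: wave speed, BFS equivalence, diagnostics.

These functions quantify the claims the model is validated against:
first-spike times order nodes like BFS hop counts (the wave implements a
parallelized breadth-first search) and the front travels about one grid
cell per millisecond.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .topology import GridManifold, bfs_distances, connectivity_graph
from .wave_layer import WaveLayer

__all__ = [
    "first_spike_vs_bfs",
    "wave_speed",
    "spike_fraction_timeline",
]


def first_spike_vs_bfs(
    layer: WaveLayer, source: int, d_e: float | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Pairs (hops, first_spike_ms) for all excitatory neurons that spiked.

    Hops are BFS distances from ``source`` on the range-``d_e`` graph
    (default: the layer's excitatory interaction range).
    """
    d_e = layer.syn.d_e if d_e is None else d_e
    graph = connectivity_graph(layer.manifold, d_e)
    dist = bfs_distances(graph, source)
    spiked = np.flatnonzero(~np.isnan(layer.first_spike_exc))
    hops = np.array([dist.get(int(i), -1) for i in spiked])
    ok = hops >= 0
    return hops[ok], layer.first_spike_exc[spiked][ok]


def wave_speed(
    layer: WaveLayer, source: int, d_e: float | None = None
) -> tuple[float, float]:
    """(speed in cells/ms, Spearman rho) from the first-spike regression.

    First-spike time is regressed on BFS hop distance; one hop covers up
    to ``d_e`` grid cells, so speed = d_e / slope.
    """
    d_e = layer.syn.d_e if d_e is None else d_e
    hops, times = first_spike_vs_bfs(layer, source, d_e)
    if len(hops) < 10:
        raise ValueError("too few spiking neurons to estimate a wave speed")
    slope = np.polyfit(hops, times, 1)[0]
    rho = stats.spearmanr(hops, times).statistic
    return float(d_e / slope), float(rho)


def spike_fraction_timeline(
    manifold: GridManifold, layer: WaveLayer, duration_ms: int
) -> np.ndarray:
    """Fraction of free excitatory neurons spiking at each of the next steps."""
    n_free = manifold.n_free
    out = np.empty(duration_ms)
    for i in range(duration_ms):
        layer.step()
        out[i] = np.count_nonzero(layer.spiked_exc) / n_free
    return out
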