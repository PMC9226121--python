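"""Layer interaction and the full planning loop.

Each millisecond the wave layer advances one step and the attractor sheet
advances one step.  When a wavefront newly enters the bump's active
region, the overlap between the two layers' active sets defines a
direction vector

    delta(t) = mean(C_t  ^  P_t) - p_t

pointing from the bump center p_t toward the centroid of the overlap,
i.e. toward the incoming front.  The vector is normalized, scaled by a
calibrated gain, applied inside the attractor kernel for a short hold
time, and then zeroed again.  A recovery period R follows each update so
that every wavefront can move the bump at most once; a new update is
armed only after the overlap has emptied (the front has left the bump
region), which keeps the trailing edge of the very front that triggered
the move from dragging the bump backward.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .attractor import (
    AttractorConfig,
    AttractorState,
    active_set,
    attractor_step,
    bump_center,
    initialize_bump,
    kernel_matrix,
)
from .errors import (
    ConfigurationError,
    DegenerateMazeError,
    InvalidNodeError,
    WavenavError,
)
from .topology import GridManifold, bfs_distances, connectivity_graph
from .wave_layer import HeterogeneityConfig, SynapseConfig, WaveLayer

__all__ = [
    "PlannerConfig",
    "PlannerRun",
    "overlap_set",
    "direction_vector",
    "apply_direction",
    "Planner",
    "run_planner",
    "path_efficiency",
]


@dataclass(frozen=True)
class PlannerConfig:
    """Parameters of the layer coupling and the run loop.

    R : recovery period in ms after each direction update.
    active_frac : relative threshold defining the bump's active set C_t.
    delta_gain : magnitude (normalized coordinates) of the applied
        direction vector; calibrated so one wavefront moves the bump a
        few nodes, bounded by half the bump width.
    delta_hold_ms : attractor steps the vector stays applied before it is
        zeroed again.
    arrival_radius : Euclidean distance (grid units) to the target below
        which the run terminates as arrived; the bump is an extended
        object, so its center saturates about half a bump width away
        from the stimulated node.
    max_steps : simulation budget in ms.
    """

    R: int = 12
    active_frac: float = 0.2
    delta_gain: float = 0.065
    delta_hold_ms: int = 2
    arrival_radius: float = 6.0
    max_steps: int = 8000

    def __post_init__(self) -> None:
        if self.R < 0:
            raise ConfigurationError("R must be nonnegative")
        if not 0.0 < self.active_frac < 1.0:
            raise ConfigurationError("active_frac must be in (0, 1)")
        if self.delta_gain <= 0:
            raise ConfigurationError("delta_gain must be positive")
        if self.delta_hold_ms < 1:
            raise ConfigurationError("delta_hold_ms must be at least 1")
        if self.arrival_radius < 0:
            raise ConfigurationError("arrival_radius must be nonnegative")
        if self.max_steps <= 0:
            raise ConfigurationError("max_steps must be positive")


@dataclass
class PlannerRun:
    """Record of one coupled simulation.

    ``trajectory`` holds (t_ms, node_id) pairs: the initial center at t=0
    plus one entry per change of the bump center.  ``path_hops`` is the
    number of distinct successive centers minus one.
    """

    trajectory: list[tuple[int, int]]
    status: str  # arrived | budget_exhausted | collapsed
    start: int
    target: int
    seed: int | None = None
    raster: list[tuple[float, str, int, int]] = field(default_factory=list)
    n_direction_updates: int = 0

    @property
    def path_hops(self) -> int:
        return len(self.trajectory) - 1

    @property
    def arrival_time_ms(self) -> int | None:
        return self.trajectory[-1][0] if self.status == "arrived" else None


def overlap_set(c_t: np.ndarray, p_t: np.ndarray) -> np.ndarray:
    """Exact intersection of the two layers' active node-id sets."""
    return np.intersect1d(c_t, p_t, assume_unique=False)


def direction_vector(
    overlap: np.ndarray, p_t: tuple[float, float], nx: int
) -> np.ndarray:
    """Mean overlap position minus bump center, in grid units.

    An empty overlap yields the zero vector (no movement).
    """
    if len(overlap) == 0:
        return np.zeros(2)
    xs = overlap % nx
    ys = overlap // nx
    return np.array([xs.mean() - p_t[0], ys.mean() - p_t[1]])


def apply_direction(raw: np.ndarray, cfg: PlannerConfig) -> np.ndarray:
    """Convert a grid-unit direction into the kernel's normalized delta.

    Only the direction of ``raw`` matters; the magnitude is the calibrated
    ``delta_gain``.  A zero vector passes through unchanged.
    """
    norm = float(np.hypot(raw[0], raw[1]))
    if norm == 0.0:
        return np.zeros(2)
    return cfg.delta_gain * np.asarray(raw, dtype=float) / norm


class Planner:
    """Coupled two-layer simulation stepped at 1 ms resolution."""

    def __init__(
        self,
        manifold: GridManifold,
        start: int,
        target: int,
        syn: SynapseConfig | None = None,
        attractor: AttractorConfig | None = None,
        planner: PlannerConfig | None = None,
        heterogeneity: HeterogeneityConfig | None = None,
        rng: np.random.Generator | None = None,
        record_raster: bool = False,
    ) -> None:
        if start == target:
            raise ConfigurationError("start and target must differ")
        for name, node in (("start", start), ("target", target)):
            if not (0 <= node < manifold.n_nodes) or not manifold.is_free(node):
                raise InvalidNodeError(f"{name} node {node} is blocked or invalid")
        self.manifold = manifold
        self.syn = syn or SynapseConfig()
        self.acfg = attractor or AttractorConfig(nx=manifold.nx, ny=manifold.ny)
        if (self.acfg.nx, self.acfg.ny) != (manifold.nx, manifold.ny):
            raise ConfigurationError(
                "attractor sheet dimensions must match the manifold"
            )
        self.pcfg = planner or PlannerConfig()
        graph = connectivity_graph(manifold, self.syn.d_e)
        dist = bfs_distances(graph, start)
        if target not in dist:
            raise DegenerateMazeError(
                f"target {target} unreachable from start {start}"
            )
        self.bfs_hops_start_target = dist[target]
        self.wave = WaveLayer(
            manifold,
            self.syn,
            stim_nodes=(target,),
            heterogeneity=heterogeneity,
            rng=rng,
            record_raster=record_raster,
        )
        self.bump = initialize_bump(start, self.acfg, manifold)
        self.start = start
        self.target = target
        self._base_kernel = kernel_matrix(self.acfg, np.zeros(2))
        self._steer_kernel: np.ndarray | None = None
        self.recovery_timer = 0
        self.hold_left = 0
        self._armed = True
        self.t = 0
        self.n_direction_updates = 0
        self.trigger_times: list[int] = []
        center = bump_center(self.bump, self.acfg)
        self.trajectory: list[tuple[int, int]] = [(0, center)]

    # -- single tick -----------------------------------------------------

    def step(self) -> None:
        """One 1-ms tick: wave step, overlap check, attractor step."""
        self.t += 1
        self.wave.step()
        p_t = bump_center(self.bump, self.acfg)
        px, py = self.manifold.node_xy(p_t)
        c_t = active_set(self.bump, self.pcfg.active_frac)
        p_set = np.flatnonzero(self.wave.spiked_exc)
        overlap = overlap_set(c_t, p_set)
        if len(overlap) == 0:
            # the front has left the bump region: a new update may arm
            self._armed = True
        elif self.recovery_timer == 0 and self._armed:
            raw = direction_vector(overlap, (px, py), self.manifold.nx)
            delta = apply_direction(raw, self.pcfg)
            if delta.any():
                self._steer_kernel = kernel_matrix(self.acfg, delta)
                self.bump.delta = delta
                self.hold_left = self.pcfg.delta_hold_ms
                self.recovery_timer = self.pcfg.R
                self._armed = False
                self.n_direction_updates += 1
                self.trigger_times.append(self.t)
        if self.hold_left > 0:
            kernel = self._steer_kernel
        else:
            kernel = self._base_kernel
            self.bump.delta = np.zeros(2)
        self.bump = attractor_step(
            self.bump, self.acfg, self.manifold.blocked_flat, kernel
        )
        if self.hold_left > 0:
            self.hold_left -= 1
        if self.recovery_timer > 0:
            self.recovery_timer -= 1
        center = bump_center(self.bump, self.acfg)
        if center != self.trajectory[-1][1]:
            self.trajectory.append((self.t, center))

    def distance_to_target(self) -> float:
        cx, cy = self.manifold.node_xy(self.trajectory[-1][1])
        tx, ty = self.manifold.node_xy(self.target)
        return float(np.hypot(cx - tx, cy - ty))

    def run(self) -> PlannerRun:
        status = "budget_exhausted"
        try:
            while self.t < self.pcfg.max_steps:
                self.step()
                if self.distance_to_target() <= self.pcfg.arrival_radius:
                    status = "arrived"
                    break
        except WavenavError:
            status = "collapsed"
        return PlannerRun(
            trajectory=self.trajectory,
            status=status,
            start=self.start,
            target=self.target,
            raster=self.wave.raster_records() if self.wave.record_raster else [],
            n_direction_updates=self.n_direction_updates,
        )


def run_planner(
    manifold: GridManifold,
    start: int,
    target: int,
    syn: SynapseConfig | None = None,
    attractor: AttractorConfig | None = None,
    planner: PlannerConfig | None = None,
    heterogeneity: HeterogeneityConfig | None = None,
    seed: int | None = None,
    record_raster: bool = False,
) -> PlannerRun:
    """Plan a route from ``start`` to ``target`` on the manifold.

    The target node is permanently DC-stimulated in the wave layer; the
    loop runs until the bump center is within ``arrival_radius`` of the
    target or the budget is exhausted.  ``seed`` feeds the heterogeneous
    randomization (ignored in the homogeneous setup, which is fully
    deterministic).
    """
    rng = np.random.default_rng(seed) if seed is not None else None
    p = Planner(
        manifold, start, target,
        syn=syn, attractor=attractor, planner=planner,
        heterogeneity=heterogeneity, rng=rng, record_raster=record_raster,
    )
    run = p.run()
    run.seed = seed
    return run


def path_efficiency(run: PlannerRun, manifold: GridManifold, d_e: float = 2.0) -> float:
    """Traversed hops relative to the BFS shortest-path oracle.

    (number of distinct successive bump centers - 1) divided by the BFS
    hop distance from start to target on the range-``d_e`` graph.
    """
    if run.status != "arrived":
        raise ConfigurationError("path efficiency is defined for arrived runs")
    graph = connectivity_graph(manifold, d_e)
    dist = bfs_distances(graph, run.start)
    hops = dist.get(run.target)
    if hops is None or hops == 0:
        raise ConfigurationError("start and target must be distinct and connected")
    return run.path_hops / hops
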