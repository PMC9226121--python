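"""Grid cognitive maps: the discretized manifold of stimuli.

The task space (positions in a maze, joint-angle pairs, ...) is modeled as a
regular quadratic grid with unit spacing.  Nodes may be blocked (walls,
forbidden states); every free node is connected to the free nodes within a
Euclidean interaction range, which yields the graph on which both neural
layers operate and on which the classical BFS oracle runs.

Conventions
-----------
* Coordinates are 0-based ``(x, y)`` with ``x`` the column and ``y`` the row.
* A node id is the flat index ``y * nx + x``.
* Masks are boolean arrays of shape ``(ny, nx)``; ``True`` means blocked.
* Distances are Euclidean on integer grid coordinates, so neighbor
  distances take values 1, sqrt(2), 2, ... in grid units.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import networkx as nx

from .errors import (
    ConfigurationError,
    DegenerateManifoldError,
    DegenerateMazeError,
    InvalidNodeError,
)

__all__ = [
    "GridManifold",
    "build_manifold",
    "neighbors_within",
    "connectivity_graph",
    "bfs_distances",
    "make_maze",
    "read_mask",
    "write_mask",
]


@dataclass(frozen=True)
class GridManifold:
    """A rectangular grid of stimuli with an obstacle mask.

    Attributes
    ----------
    nx, ny : int
        Grid extent in x (columns) and y (rows); both at least 3.
    blocked : ndarray of bool, shape (ny, nx)
        ``True`` marks nodes that cannot be traversed.
    """

    nx: int
    ny: int
    blocked: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if self.nx < 3 or self.ny < 3:
            raise ConfigurationError(
                f"grid must be at least 3x3, got {self.nx}x{self.ny}"
            )
        blocked = np.asarray(self.blocked, dtype=bool)
        if blocked.shape != (self.ny, self.nx):
            raise ConfigurationError(
                f"blocked mask shape {blocked.shape} does not match "
                f"grid (ny={self.ny}, nx={self.nx})"
            )
        blocked = blocked.copy()
        blocked.setflags(write=False)
        object.__setattr__(self, "blocked", blocked)
        if self.n_free < 2:
            raise DegenerateManifoldError(
                "manifold needs at least two free nodes"
            )

    # -- basic queries ---------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return self.nx * self.ny

    @property
    def n_free(self) -> int:
        return int(self.n_nodes - np.count_nonzero(self.blocked))

    @property
    def blocked_flat(self) -> np.ndarray:
        return self.blocked.reshape(-1)

    def node_id(self, x: int, y: int) -> int:
        if not (0 <= x < self.nx and 0 <= y < self.ny):
            raise InvalidNodeError(f"({x}, {y}) outside {self.nx}x{self.ny} grid")
        return y * self.nx + x

    def node_xy(self, node: int) -> tuple[int, int]:
        if not (0 <= node < self.n_nodes):
            raise InvalidNodeError(f"node id {node} outside grid")
        return node % self.nx, node // self.nx

    def is_free(self, node: int) -> bool:
        return not bool(self.blocked_flat[node])

    def coords(self) -> np.ndarray:
        """(n_nodes, 2) array of (x, y) positions, indexed by node id."""
        xs = np.tile(np.arange(self.nx), self.ny)
        ys = np.repeat(np.arange(self.ny), self.nx)
        return np.stack([xs, ys], axis=1)


def build_manifold(nx: int, ny: int, blocked: np.ndarray | None = None) -> GridManifold:
    """Validate and build a :class:`GridManifold`.

    ``blocked=None`` means a fully open grid.
    """
    if blocked is None:
        blocked = np.zeros((ny, nx), dtype=bool)
    return GridManifold(nx=nx, ny=ny, blocked=np.asarray(blocked, dtype=bool))


def _offsets_within(radius: float) -> list[tuple[int, int, float]]:
    """Integer lattice offsets (dx, dy, d) with 0 < d <= radius."""
    r = int(np.floor(radius))
    out = []
    for dx in range(-r, r + 1):
        for dy in range(-r, r + 1):
            d = float(np.hypot(dx, dy))
            if 0.0 < d <= radius:
                out.append((dx, dy, d))
    return out


def neighbors_within(
    manifold: GridManifold, node: int, radius: float
) -> list[tuple[int, float]]:
    """Free neighbors of ``node`` with Euclidean distance 0 < d <= radius.

    The node itself and blocked nodes are excluded; distances are exact.
    """
    if radius <= 0:
        raise ConfigurationError("radius must be positive")
    if not manifold.is_free(node):
        raise InvalidNodeError(f"node {node} is blocked")
    x, y = manifold.node_xy(node)
    out = []
    for dx, dy, d in _offsets_within(radius):
        px, py = x + dx, y + dy
        if 0 <= px < manifold.nx and 0 <= py < manifold.ny:
            if not manifold.blocked[py, px]:
                out.append((py * manifold.nx + px, d))
    return out


def connectivity_graph(manifold: GridManifold, radius: float) -> nx.Graph:
    """Undirected graph over free nodes with edges for 0 < d <= radius.

    Edge attribute ``distance`` stores the Euclidean length.
    """
    g = nx.Graph()
    blocked = manifold.blocked
    free_ids = np.flatnonzero(~manifold.blocked_flat)
    g.add_nodes_from(free_ids.tolist())
    for dx, dy, d in _offsets_within(radius):
        if dx < 0 or (dx == 0 and dy < 0):
            continue  # add each undirected edge once
        x0, x1 = max(0, -dx), min(manifold.nx, manifold.nx - dx)
        y0, y1 = max(0, -dy), min(manifold.ny, manifold.ny - dy)
        if x0 >= x1 or y0 >= y1:
            continue
        sx, sy = np.meshgrid(np.arange(x0, x1), np.arange(y0, y1))
        ok = ~blocked[sy, sx] & ~blocked[sy + dy, sx + dx]
        src = (sy[ok] * manifold.nx + sx[ok]).ravel()
        dst = ((sy[ok] + dy) * manifold.nx + (sx[ok] + dx)).ravel()
        g.add_edges_from(
            (int(a), int(b), {"distance": d}) for a, b in zip(src, dst)
        )
    return g


def bfs_distances(graph: nx.Graph, source: int) -> dict[int, int]:
    """Unweighted BFS hop counts from ``source`` over the connectivity graph.

    Nodes not reachable from ``source`` are absent from the result.  This is
    the classical-algorithm oracle the traveling waves are validated against:
    the wavefront visits nodes in order of exactly these hop counts.
    """
    if source not in graph:
        raise InvalidNodeError(f"source {source} not a free node of the graph")
    return dict(nx.single_source_shortest_path_length(graph, source))


# ---------------------------------------------------------------------------
# maze generators
# ---------------------------------------------------------------------------

#: Walls are at least this thick so that interaction ranges up to 2 grid
#: units can never tunnel through a wall (an edge of length 2 would
#: otherwise connect the two free cells flanking a 1-cell wall).
WALL_THICKNESS = 2

MAZE_KINDS = ("open", "s_maze", "blocks", "fine_structure")


def make_maze(
    kind: str,
    nx_: int,
    ny_: int,
    *,
    start: tuple[int, int] | None = None,
    target: tuple[int, int] | None = None,
    interaction_range: float = 2.0,
) -> np.ndarray:
    """Deterministic obstacle masks reproducing the study's maze topologies.

    Parameters
    ----------
    kind : {"open", "s_maze", "blocks", "fine_structure"}
        ``open``: no obstacles.  ``s_maze``: two interleaved horizontal
        walls forcing an S-shaped corridor.  ``blocks``: rectangular
        obstacles in an otherwise open field.  ``fine_structure``: a
        comb-shaped multi-corridor labyrinth.
    start, target : (x, y), optional
        If given, the generated maze is checked to keep both free and
        mutually reachable on the range-``interaction_range`` graph.

    Returns
    -------
    ndarray of bool, shape (ny, nx); True = blocked.
    """
    if kind not in MAZE_KINDS:
        raise ConfigurationError(
            f"unknown maze kind {kind!r}; expected one of {MAZE_KINDS}"
        )
    mask = np.zeros((ny_, nx_), dtype=bool)
    t = WALL_THICKNESS
    if kind == "open":
        pass
    elif kind == "s_maze":
        if nx_ < 20 or ny_ < 20:
            raise ConfigurationError("s_maze needs a grid of at least 20x20")
        # two horizontal walls at 1/3 and 2/3 height, attached to opposite
        # sides, each leaving a corridor of about a quarter grid width open
        gap = max(6, nx_ // 4)
        y1 = ny_ // 3
        y2 = 2 * ny_ // 3
        mask[y1 : y1 + t, 0 : nx_ - gap] = True
        mask[y2 : y2 + t, gap:nx_] = True
    elif kind == "blocks":
        if nx_ < 30 or ny_ < 30:
            raise ConfigurationError("blocks needs a grid of at least 30x30")
        # one large central block and one offset block near the top edge
        cx0, cy0 = round(nx_ * 0.32), round(ny_ * 0.32)
        cx1, cy1 = round(nx_ * 0.66), round(ny_ * 0.66)
        mask[cy0:cy1, cx0:cx1] = True
        mask[round(ny_ * 0.05) : round(ny_ * 0.22),
             round(nx_ * 0.49) : round(nx_ * 0.83)] = True
    elif kind == "fine_structure":
        if nx_ < 30 or ny_ < 30:
            raise ConfigurationError("fine_structure needs a grid of at least 30x30")
        # comb labyrinth: vertical walls with alternating top/bottom gaps,
        # forcing a serpentine corridor across the whole grid
        period = 8
        corridor = 9
        k = 0
        for x in range(period - 1, nx_ - (t + 2), period):
            if k % 2 == 0:
                mask[0 : ny_ - corridor, x : x + t] = True
            else:
                mask[corridor:ny_, x : x + t] = True
            k += 1
    if start is not None and target is not None:
        _check_reachable(mask, start, target, interaction_range)
    return mask


def _check_reachable(
    mask: np.ndarray,
    start: tuple[int, int],
    target: tuple[int, int],
    radius: float,
) -> None:
    ny_, nx_ = mask.shape
    m = build_manifold(nx_, ny_, mask)
    for name, (x, y) in (("start", start), ("target", target)):
        if mask[y, x]:
            raise DegenerateMazeError(f"{name} node ({x}, {y}) is blocked")
    g = connectivity_graph(m, radius)
    dist = bfs_distances(g, m.node_id(*start))
    if m.node_id(*target) not in dist:
        raise DegenerateMazeError(
            f"target {target} unreachable from start {start}"
        )


# ---------------------------------------------------------------------------
# mask file format: '.' free, '#' blocked, one row per line
# ---------------------------------------------------------------------------

def write_mask(path: str | Path, mask: np.ndarray) -> None:
    mask = np.asarray(mask, dtype=bool)
    lines = ["".join("#" if b else "." for b in row) for row in mask]
    Path(path).write_text("\n".join(lines) + "\n")


def read_mask(path: str | Path) -> np.ndarray:
    lines = [ln for ln in Path(path).read_text().splitlines() if ln]
    if not lines:
        raise ConfigurationError(f"empty mask file: {path}")
    width = len(lines[0])
    rows = []
    for i, ln in enumerate(lines):
        if len(ln) != width:
            raise ConfigurationError(
                f"{path}: line {i + 1} has length {len(ln)}, expected {width}"
            )
        bad = set(ln) - {".", "#"}
        if bad:
            raise ConfigurationError(
                f"{path}: line {i + 1} contains invalid characters {bad!r}"
            )
        rows.append([c == "#" for c in ln])
    return np.asarray(rows, dtype=bool)
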