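"""Continuous attractor layer: a rate-coded place-cell sheet.

Each node of the grid carries one rate-coded neuron.  The recurrent kernel
is a shifted Gaussian — short-range excitation minus a uniform inhibitory
offset — which sustains a single localized bump of activity representing
the current position on the manifold.  A direction vector added inside the
kernel biases the connectivity and makes the bump drift, which is how the
wave layer steers it.

Kernel (offsets in sheet-normalized coordinates)::

    w(i, j) = J exp(-|| ((i_x - j_x)/N_x, (i_y - j_y)/N_y) + delta ||^2
                    / sigma^2) - T

Update: the recurrent drive ``B_j = sum_i A_i w(i, j)`` is normalized by
the total activation and the sheet relaxes toward it::

    A_j(t+1) = (1 - tau) A_j(t) + tau * B_j(t+1) / sum_i A_i(t)

with negative rates clipped to zero and blocked nodes clamped to zero.
The stationary bump is the dominant eigenprofile of the clipped kernel and
its amplitude the corresponding eigenvalue, so the relaxation is a damped
power iteration; ``tau`` sets how strongly each step pulls toward the
normalized recurrent drive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import (
    CollapsedBumpError,
    ConfigurationError,
    InitializationError,
    InvalidNodeError,
)
from .topology import GridManifold

__all__ = [
    "AttractorConfig",
    "AttractorState",
    "attractor_weight",
    "kernel_matrix",
    "attractor_step",
    "initialize_bump",
    "bump_center",
    "active_set",
    "bump_diameter",
]


@dataclass(frozen=True)
class AttractorConfig:
    """Parameters of the place-cell sheet.

    sigma : Gaussian width in sheet-normalized coordinate units.
    T     : uniform inhibitory shift subtracted from the kernel.
    J     : kernel strength scale.
    tau   : relaxation weight toward the normalized recurrent drive.
    nx, ny: sheet dimensions (match the wave layer's grid).
    relax_tol, relax_budget : convergence criterion for bump initialization.
    """

    sigma: float = 0.03
    T: float = 0.05
    J: float = 12.0
    tau: float = 0.8
    nx: int = 41
    ny: int = 41
    relax_tol: float = 1e-6
    relax_budget: int = 2000

    def __post_init__(self) -> None:
        if self.J <= 0 or self.sigma <= 0:
            raise ConfigurationError("J and sigma must be positive")
        if self.T < 0:
            raise ConfigurationError("T must be nonnegative")
        if not 0.0 <= self.tau <= 1.0:
            raise ConfigurationError("tau must be in [0, 1]")


@dataclass
class AttractorState:
    """Activation field plus the current steering vector."""

    A: np.ndarray
    delta: np.ndarray = field(default_factory=lambda: np.zeros(2))
    t: float = 0.0

    def total(self) -> float:
        return float(self.A.sum())


def attractor_weight(
    i: tuple[int, int],
    j: tuple[int, int],
    delta: tuple[float, float],
    cfg: AttractorConfig,
) -> float:
    """Single synaptic weight from neuron at i to neuron at j (exact)."""
    ox = (i[0] - j[0]) / cfg.nx + delta[0]
    oy = (i[1] - j[1]) / cfg.ny + delta[1]
    return cfg.J * np.exp(-(ox * ox + oy * oy) / cfg.sigma**2) - cfg.T


def kernel_matrix(cfg: AttractorConfig, delta: np.ndarray) -> np.ndarray:
    """Dense (n, n) weight matrix W[i, j] for the whole sheet.

    The weight depends only on the coordinate offset i - j, so the matrix
    is assembled by indexing a (2 ny - 1, 2 nx - 1) offset table, which
    keeps rebuilds cheap when the direction vector changes.
    """
    nx_, ny_ = cfg.nx, cfg.ny
    dx = np.arange(-(nx_ - 1), nx_) / nx_ + float(delta[0])
    dy = np.arange(-(ny_ - 1), ny_) / ny_ + float(delta[1])
    gx = np.exp(-(dx * dx)[None, :] / cfg.sigma**2)
    gy = np.exp(-(dy * dy)[:, None] / cfg.sigma**2)
    table = cfg.J * (gy * gx) - cfg.T  # [dy + ny - 1, dx + nx - 1]
    xs = np.tile(np.arange(nx_), ny_)
    ys = np.repeat(np.arange(ny_), nx_)
    ox = xs[:, None] - xs[None, :] + (nx_ - 1)
    oy = ys[:, None] - ys[None, :] + (ny_ - 1)
    return table[oy, ox]


def attractor_step(
    state: AttractorState,
    cfg: AttractorConfig,
    blocked: np.ndarray | None = None,
    kernel: np.ndarray | None = None,
) -> AttractorState:
    """Advance the sheet by one step under the state's direction vector.

    Raises :class:`CollapsedBumpError` if total activation is zero (the
    normalization is undefined and the position estimate is lost).
    """
    total = state.total()
    if total <= 0.0:
        raise CollapsedBumpError("total activation is zero")
    if kernel is None:
        kernel = kernel_matrix(cfg, state.delta)
    drive = state.A @ kernel
    new_a = (1.0 - cfg.tau) * state.A + cfg.tau * drive / total
    np.clip(new_a, 0.0, None, out=new_a)
    if blocked is not None:
        new_a[np.asarray(blocked).reshape(-1)] = 0.0
    return AttractorState(A=new_a, delta=state.delta.copy(), t=state.t + 1.0)


def initialize_bump(
    start: int,
    cfg: AttractorConfig,
    manifold: GridManifold | None = None,
) -> AttractorState:
    """Seed one node and relax (delta = 0) to the stationary bump.

    Deterministic: no randomness enters the relaxation.  Raises
    :class:`InitializationError` if the fixed point is not reached within
    the configured budget.
    """
    blocked = manifold.blocked_flat if manifold is not None else None
    n = cfg.nx * cfg.ny
    if not 0 <= start < n:
        raise InvalidNodeError(f"start node {start} outside sheet")
    if blocked is not None and blocked[start]:
        raise InvalidNodeError(f"start node {start} is blocked")
    state = AttractorState(A=np.zeros(n))
    state.A[start] = 1.0
    kernel = kernel_matrix(cfg, np.zeros(2))
    for _ in range(cfg.relax_budget):
        new = attractor_step(state, cfg, blocked, kernel)
        change = float(np.abs(new.A - state.A).max())
        new.t = 0.0
        state = new
        if change < cfg.relax_tol:
            return state
    raise InitializationError(
        f"bump relaxation did not converge within {cfg.relax_budget} steps"
    )


def bump_center(state: AttractorState, cfg: AttractorConfig) -> int:
    """Node id of the activation maximum; ties break to the smallest id."""
    if state.total() <= 0.0:
        raise CollapsedBumpError("cannot locate center of a collapsed bump")
    return int(np.argmax(state.A))


def active_set(state: AttractorState, frac: float) -> np.ndarray:
    """Node ids with activation >= frac * max(A) (the set C_t)."""
    if not 0.0 < frac < 1.0:
        raise ConfigurationError("frac must be in (0, 1)")
    peak = float(state.A.max())
    if state.total() <= 0.0 or peak <= 0.0:
        raise CollapsedBumpError("active set of a collapsed bump")
    return np.flatnonzero(state.A >= frac * peak)


def bump_diameter(
    state: AttractorState, cfg: AttractorConfig, frac: float = 0.1
) -> int:
    """Extent (in nodes) of the active set along x through the bump center."""
    center = bump_center(state, cfg)
    cy = center // cfg.nx
    ids = active_set(state, frac)
    row = ids[ids // cfg.nx == cy] % cfg.nx
    return int(row.max() - row.min() + 1)
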