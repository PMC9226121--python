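"""Spiking wave-propagation layer.

One excitatory and one inhibitory Izhikevich neuron sit on every grid node.
Excitatory neurons drive their neighborhood with 1/d-decaying synapses;
inhibitory partners are driven by nearby excitatory spikes and suppress the
surrounding excitatory cells, which confines activity to a thin expanding
front.  Permanent DC stimulation of the target node makes it spike
regularly, so it emits repeated, roughly circular wavefronts that sweep the
whole free grid — a parallelized breadth-first search whose first-spike
times order nodes by hop distance from the stimulated node.

Membrane dynamics (per neuron, time in ms, one forward-Euler step per ms)::

    dv/dt = 0.04 v^2 + 5 v + 140 - u + I
    du/dt = a (b v - u)
    if v >= 30: spike; v <- c, u <- u + d

Spikes emitted at step t are delivered as delta currents at step t + 1;
there is no synaptic transmission delay or temporal filtering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse

from .errors import ConfigurationError, NumericalDivergenceError
from .topology import GridManifold, _offsets_within

__all__ = [
    "IzhikevichParams",
    "RS",
    "FS",
    "SynapseConfig",
    "HeterogeneityConfig",
    "NeuronArrays",
    "synaptic_strength_ee",
    "synaptic_strength_ei",
    "synaptic_strength_ie",
    "build_synapses",
    "izhikevich_step",
    "randomize_neuron_params",
    "jitter_synapses",
    "WaveLayer",
]

#: Spike threshold in mV.
V_SPIKE = 30.0
#: Resting membrane potential used for deterministic initialization.
V_REST = -70.0


@dataclass(frozen=True)
class IzhikevichParams:
    """Phenotype parameters (a, b, c, d) of the two-variable neuron model."""

    a: float
    b: float
    c: float
    d: float

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0:
            raise ConfigurationError("Izhikevich a and b must be positive")


#: Regular-spiking excitatory phenotype.
RS = IzhikevichParams(a=0.02, b=0.2, c=-65.0, d=8.0)
#: Fast-spiking inhibitory phenotype.
FS = IzhikevichParams(a=0.1, b=0.2, c=-65.0, d=2.0)


@dataclass(frozen=True)
class SynapseConfig:
    """Strengths and ranges of the three synapse classes in the wave layer.

    ``s_ee_max`` is the peak excitatory-to-excitatory strength; the
    excitatory-to-inhibitory and inhibitory-to-excitatory peaks are
    expressed as multiples of it.  All strengths decay as 1/d with the
    Euclidean node distance d and are cut off beyond their range
    (``d_e`` for e->e, ``d_i`` for e->i, ``d_s`` for i->e).  The i->e
    synapse additionally has its full (negative) peak at d = 0: each
    inhibitory neuron suppresses its co-located excitatory partner.

    ``v_floor`` clamps the membrane potential from below.  Strong
    inhibitory delta currents would otherwise push an Euler-integrated
    neuron past the lower branch of the quadratic nullcline, where the
    v^2 term makes the explicit scheme blow up.
    """

    s_ee_max: float = 50.0
    s_ei_factor: float = 0.5
    s_ie_factor: float = -9.0
    d_e: float = 2.0
    d_i: float = 1.0
    d_s: float = 1.0
    I_dc: float = 25.0
    v_floor: float = -90.0

    def __post_init__(self) -> None:
        if self.s_ee_max <= 0:
            raise ConfigurationError("s_ee_max must be positive")
        if self.s_ie_factor >= 0:
            raise ConfigurationError("s_ie_factor must be negative (suppressive)")
        if self.d_e <= 0 or self.d_i <= 0 or self.d_s <= 0:
            raise ConfigurationError("interaction ranges must be positive")

    @property
    def s_ei_max(self) -> float:
        return self.s_ei_factor * self.s_ee_max

    @property
    def s_ie_max(self) -> float:
        return self.s_ie_factor * self.s_ee_max


@dataclass(frozen=True)
class HeterogeneityConfig:
    """Switch for the biologically-variable network configuration.

    When enabled, every neuron draws its phenotype between regular spiking
    and chattering (excitatory, biased toward RS by squaring the draw) or
    between low-threshold spiking and fast spiking (inhibitory), and every
    nonzero synaptic weight is jittered by up to +-``jitter_fraction``.
    """

    enabled: bool = False
    jitter_fraction: float = 0.10

    def __post_init__(self) -> None:
        if not 0.0 <= self.jitter_fraction < 1.0:
            raise ConfigurationError("jitter_fraction must be in [0, 1)")


# ---------------------------------------------------------------------------
# synaptic strength profiles
# ---------------------------------------------------------------------------

def synaptic_strength_ee(d: float, cfg: SynapseConfig) -> float:
    """Excitatory->excitatory strength at node distance d (0 at d = 0)."""
    if d < 0:
        raise ConfigurationError("distance must be nonnegative")
    if 0.0 < d <= cfg.d_e:
        return cfg.s_ee_max / d
    return 0.0


def synaptic_strength_ei(d: float, cfg: SynapseConfig) -> float:
    """Excitatory->inhibitory strength at node distance d (0 at d = 0)."""
    if d < 0:
        raise ConfigurationError("distance must be nonnegative")
    if 0.0 < d <= cfg.d_i:
        return cfg.s_ei_max / d
    return 0.0


def synaptic_strength_ie(d: float, cfg: SynapseConfig) -> float:
    """Inhibitory->excitatory strength; full negative peak at d = 0."""
    if d < 0:
        raise ConfigurationError("distance must be nonnegative")
    if d == 0.0:
        return cfg.s_ie_max
    if d <= cfg.d_s:
        return cfg.s_ie_max / d
    return 0.0


def build_synapses(
    manifold: GridManifold, cfg: SynapseConfig
) -> tuple[sparse.csr_matrix, sparse.csr_matrix, sparse.csr_matrix]:
    """Sparse weight matrices (W_ee, W_ei, W_ie) for the manifold.

    ``W[j, i]`` is the strength from presynaptic neuron i to postsynaptic
    neuron j, so currents are ``W @ spikes``.  Blocked nodes have all
    incoming and outgoing weights zeroed.
    """
    n = manifold.n_nodes
    blocked = manifold.blocked
    rmax = max(cfg.d_e, cfg.d_i, cfg.d_s)
    ent: dict[str, list[tuple[np.ndarray, np.ndarray, float]]] = {
        "ee": [], "ei": [], "ie": []
    }
    offsets = _offsets_within(rmax) + [(0, 0, 0.0)]
    for dx, dy, d in offsets:
        x0, x1 = max(0, -dx), min(manifold.nx, manifold.nx - dx)
        y0, y1 = max(0, -dy), min(manifold.ny, manifold.ny - dy)
        if x0 >= x1 or y0 >= y1:
            continue
        sx, sy = np.meshgrid(np.arange(x0, x1), np.arange(y0, y1))
        ok = ~blocked[sy, sx] & ~blocked[sy + dy, sx + dx]
        src = (sy[ok] * manifold.nx + sx[ok]).ravel()
        dst = ((sy[ok] + dy) * manifold.nx + (sx[ok] + dx)).ravel()
        for key, fn in (
            ("ee", synaptic_strength_ee),
            ("ei", synaptic_strength_ei),
            ("ie", synaptic_strength_ie),
        ):
            w = fn(d, cfg)
            if w != 0.0:
                ent[key].append((src, dst, w))
    mats = []
    for key in ("ee", "ei", "ie"):
        if ent[key]:
            rows = np.concatenate([dst for _, dst, _ in ent[key]])
            cols = np.concatenate([src for src, _, _ in ent[key]])
            vals = np.concatenate(
                [np.full(src.size, w) for src, _, w in ent[key]]
            )
            mats.append(sparse.csr_matrix((vals, (rows, cols)), shape=(n, n)))
        else:
            mats.append(sparse.csr_matrix((n, n)))
    return tuple(mats)


# ---------------------------------------------------------------------------
# neuron state and integration
# ---------------------------------------------------------------------------

@dataclass
class NeuronArrays:
    """Per-neuron Izhikevich parameters as arrays (allows heterogeneity)."""

    a: np.ndarray
    b: np.ndarray
    c: np.ndarray
    d: np.ndarray

    @classmethod
    def uniform(cls, n: int, p: IzhikevichParams) -> "NeuronArrays":
        return cls(
            a=np.full(n, p.a), b=np.full(n, p.b),
            c=np.full(n, p.c), d=np.full(n, p.d),
        )


def izhikevich_step(
    v: np.ndarray,
    u: np.ndarray,
    params: NeuronArrays,
    current: np.ndarray,
    dt: float = 1.0,
    v_floor: float | None = -90.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One forward-Euler step of the coupled (v, u) dynamics.

    Returns updated (v, u, spiked).  Neurons crossing the 30 mV threshold
    are flagged, reset to c and have their recovery variable bumped by d.
    """
    if dt <= 0:
        raise ConfigurationError("dt must be positive")
    v = v + dt * (0.04 * v * v + 5.0 * v + 140.0 - u + current)
    if v_floor is not None:
        np.maximum(v, v_floor, out=v)
    u = u + dt * params.a * (params.b * v - u)
    if not np.isfinite(v).all():
        raise NumericalDivergenceError("membrane potential became non-finite")
    spiked = v >= V_SPIKE
    v = np.where(spiked, params.c, v)
    u = np.where(spiked, u + params.d, u)
    return v, u, spiked


def randomize_neuron_params(
    n: int, rng: np.random.Generator
) -> tuple[NeuronArrays, NeuronArrays]:
    """Heterogeneous per-neuron phenotypes for both populations.

    Excitatory neurons interpolate RS -> chattering via r_e^2 (biased toward
    RS); inhibitory neurons interpolate LTS -> FS linearly in r_i::

        exc: c = -65 + 15 r_e^2,  d = 8 - 6 r_e^2
        inh: a = 0.02 + 0.08 r_i, b = 0.25 - 0.05 r_i
    """
    r_e = rng.uniform(0.0, 1.0, n)
    r_i = rng.uniform(0.0, 1.0, n)
    exc = NeuronArrays(
        a=np.full(n, 0.02),
        b=np.full(n, 0.2),
        c=-65.0 + 15.0 * r_e**2,
        d=8.0 - 6.0 * r_e**2,
    )
    inh = NeuronArrays(
        a=0.02 + 0.08 * r_i,
        b=0.25 - 0.05 * r_i,
        c=np.full(n, -65.0),
        d=np.full(n, 2.0),
    )
    return exc, inh


def jitter_synapses(
    weights: sparse.csr_matrix,
    rng: np.random.Generator,
    fraction: float = 0.10,
) -> sparse.csr_matrix:
    """Multiply every stored weight by (1 + eps), eps ~ U[-fraction, fraction].

    Zeros stay zero (they are not stored); signs are preserved for any
    fraction < 1.
    """
    if not 0.0 <= fraction < 1.0:
        raise ConfigurationError("fraction must be in [0, 1)")
    out = weights.copy()
    if fraction > 0.0 and out.nnz:
        out.data = out.data * (1.0 + rng.uniform(-fraction, fraction, out.nnz))
    return out


class WaveLayer:
    """Paired excitatory/inhibitory Izhikevich sheets on a grid manifold.

    Parameters
    ----------
    manifold : GridManifold
        Grid with obstacle mask; blocked nodes are disconnected.
    syn : SynapseConfig
        Synaptic strengths/ranges and the DC stimulation amplitude.
    stim_nodes : iterable of int
        Node ids receiving the permanent DC current (the target node(s)).
    heterogeneity : HeterogeneityConfig, optional
        If enabled, phenotypes and weights are randomized with ``rng``.
    rng : numpy Generator, optional
        Required when heterogeneity is enabled.
    record_raster : bool
        Keep per-step spike lists for raster export.

    All neurons start at the deterministic rest state v = -70, u = b * v,
    which is an exact fixed point of the RS/FS dynamics at zero input.
    """

    def __init__(
        self,
        manifold: GridManifold,
        syn: SynapseConfig | None = None,
        stim_nodes: tuple[int, ...] = (),
        heterogeneity: HeterogeneityConfig | None = None,
        rng: np.random.Generator | None = None,
        record_raster: bool = False,
    ) -> None:
        self.manifold = manifold
        self.syn = syn or SynapseConfig()
        self.stim_nodes = tuple(int(s) for s in stim_nodes)
        for s in self.stim_nodes:
            if not manifold.is_free(s):
                raise ConfigurationError(f"stimulated node {s} is blocked")
        n = manifold.n_nodes
        self.w_ee, self.w_ei, self.w_ie = build_synapses(manifold, self.syn)
        het = heterogeneity or HeterogeneityConfig()
        if het.enabled:
            if rng is None:
                raise ConfigurationError(
                    "heterogeneous configuration requires an rng"
                )
            for name in ("w_ee", "w_ei", "w_ie"):
                setattr(
                    self, name,
                    jitter_synapses(getattr(self, name), rng, het.jitter_fraction),
                )
            self.exc_params, self.inh_params = randomize_neuron_params(n, rng)
        else:
            self.exc_params = NeuronArrays.uniform(n, RS)
            self.inh_params = NeuronArrays.uniform(n, FS)
        self.v_exc = np.full(n, V_REST)
        self.u_exc = self.exc_params.b * self.v_exc
        self.v_inh = np.full(n, V_REST)
        self.u_inh = self.inh_params.b * self.v_inh
        self.spiked_exc = np.zeros(n, dtype=bool)
        self.spiked_inh = np.zeros(n, dtype=bool)
        self.t = 0.0
        self.first_spike_exc = np.full(n, np.nan)
        self.record_raster = record_raster
        self.raster_exc: list[tuple[float, np.ndarray]] = []
        self.raster_inh: list[tuple[float, np.ndarray]] = []
        self._stim_current = np.zeros(n)
        self._stim_current[list(self.stim_nodes)] = self.syn.I_dc

    def gather_synaptic_input(self) -> tuple[np.ndarray, np.ndarray]:
        """Input currents for (excitatory, inhibitory) populations.

        Sums incoming strengths from neurons that spiked on the previous
        step, plus the DC stimulation current for driven nodes.
        """
        se = self.spiked_exc.astype(float)
        si = self.spiked_inh.astype(float)
        i_exc = self.w_ee @ se + self.w_ie @ si + self._stim_current
        i_inh = self.w_ei @ se
        return i_exc, i_inh

    def step(self, dt: float = 1.0) -> None:
        """Advance both populations by one time step (default 1 ms)."""
        i_exc, i_inh = self.gather_synaptic_input()
        self.v_exc, self.u_exc, self.spiked_exc = izhikevich_step(
            self.v_exc, self.u_exc, self.exc_params, i_exc, dt,
            self.syn.v_floor,
        )
        self.v_inh, self.u_inh, self.spiked_inh = izhikevich_step(
            self.v_inh, self.u_inh, self.inh_params, i_inh, dt,
            self.syn.v_floor,
        )
        self.t += dt
        newly = self.spiked_exc & np.isnan(self.first_spike_exc)
        self.first_spike_exc[newly] = self.t
        if self.record_raster:
            if self.spiked_exc.any():
                self.raster_exc.append(
                    (self.t, np.flatnonzero(self.spiked_exc))
                )
            if self.spiked_inh.any():
                self.raster_inh.append(
                    (self.t, np.flatnonzero(self.spiked_inh))
                )

    def run(self, duration_ms: int) -> None:
        for _ in range(int(duration_ms)):
            self.step()

    def raster_records(self) -> list[tuple[float, str, int, int]]:
        """Raster as (t_ms, population, node_x, node_y) rows."""
        rows = []
        for pop, rast in (("exc", self.raster_exc), ("inh", self.raster_inh)):
            for t, ids in rast:
                for node in ids:
                    x, y = self.manifold.node_xy(int(node))
                    rows.append((t, pop, x, y))
        rows.sort(key=lambda r: (r[0], r[1], r[3], r[2]))
        return rows
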