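# Methods

## Model overview

`wavenav` simulates planning on a discretized manifold of stimuli: a
regular quadratic grid (default 41×41, spacing 1) whose nodes may be
blocked. Two neural layers share this grid.

**Wave propagation layer (P).** Paired excitatory/inhibitory Izhikevich
neurons per node, integrated by one forward-Euler step per 1 ms tick.
Spikes from step t are delivered as instantaneous delta currents at step
t+1; there is no transmission delay or synaptic filtering. Synaptic
strengths decay as 1/d with Euclidean node distance d and vanish beyond a
class-specific range:

| class | peak              | range | default |
|-------|-------------------|-------|---------|
| e→e   | s_ee = 50         | d_e   | 2       |
| e→i   | 0.5·s_ee = 25     | d_i   | 1       |
| i→e   | −9·s_ee = −450 (full peak also at d = 0) | d_s | 1 |

d = 0 gives zero weight for e→e and e→i (no self-excitation); the i→e
synapse keeps its full peak at d = 0, so each inhibitory neuron vetoes its
co-located excitatory partner. The homogeneous phenotypes are regular
spiking (a=0.02, b=0.2, c=−65, d=8) for excitatory and fast spiking
(a=0.1, b=0.2, c=−65, d=2) for inhibitory neurons. A permanently
stimulated node receives I_dc = 25 every step. All neurons start from the
exact rest point v = −70, u = b·v, so the unstimulated layer is silent
indefinitely and every run is reproducible.

Only d_e and the peak strengths are fixed by the reference parameter set;
the two inhibitory ranges are free parameters of this implementation.
They were chosen by behavior: d_i = d_s = 1 is the geometry at which a
single stimulated node emits clean repeating rings that cover the whole
grid (~1 cell/ms, peak spike fraction ≈ 8 %), while wider inhibitory
ranges quench the front after a few rings and weaker inhibitory peaks let
the layer avalanche into whole-grid synchrony.

**Numerical guard.** The i→e currents are hundreds of units strong for a
1 ms Euler step. A neuron kicked far below rest lands outside the basin
of the quadratic nullclines, where the 0.04 v² term catapults it into a
spurious spike (and eventually overflow). We therefore clamp v ≥ −90 mV —
roughly a potassium reversal potential — after each integration step.
With the clamp the dynamics are stable for every configuration we probed;
without it they diverge within ~200 ms.

**Continuous attractor layer (C).** One rate-coded unit per node with the
shifted-Gaussian kernel

    w(i,j) = J exp(−‖((ix−jx)/Nx, (iy−jy)/Ny) + Δ(t)‖² / σ²) − T

(J = 12, σ = 0.03 in sheet-normalized units, T = 0.05). The update first
accumulates the recurrent drive B_j = Σ_i A_i w(i,j), then relaxes the
activation toward the sum-normalized drive,

    A(t+1) = (1 − τ) A(t) + τ B(t+1) / Σ_i A_i(t),    τ = 0.8,

with negative rates clipped to zero and blocked nodes clamped to zero.
This update is a damped power iteration: its fixed point satisfies
A = B/ΣA, i.e. the bump is the dominant eigenprofile of the clipped
kernel, with amplitude equal to the eigenvalue. A purely linear
accumulation of B is not an option at these parameter values — the
local kernel gain is far above 1/(1−τ), so no positive fixed point would
exist — whereas the normalized relaxation is scale-free and
unconditionally convergent in practice. The relaxed bump is Gaussian,
11 cells across at 10 % of peak (the "effective diameter of about
twelve neurons"), unimodal, and translation-equivariant away from
boundaries. The sheet is planar (non-periodic); kernel sums truncate at
the edges.

Bump initialization seeds one node and relaxes with Δ = 0 until
max|ΔA| < 1e−6 (budget 2000 steps). Near corners the slowest mode decays
at ≈0.9965/step, so tighter tolerances would need several thousand steps
while the bump's center, shape and diameter are stationary after ~200.

## Layer coupling

Each 1 ms tick: the wave layer steps; the active sets are compared;
the attractor steps. C_t is every node with A ≥ active_frac·max(A)
(active_frac = 0.2), P_t is the excitatory neurons spiking this tick.
When the overlap A_t = C_t ∩ P_t is nonempty, the direction vector

    Δraw = mean(A_t) − p_t

points from the bump center p_t toward the overlap centroid. It is
normalized to unit length, scaled to delta_gain = 0.065 (normalized
coordinates), applied inside the kernel for delta_hold_ms = 2 steps, and
then zeroed. Two rules ensure one movement per wavefront:

- a recovery period R = 12 ms after each update, during which the overlap
  is ignored (R ≈ bump diameter / wave speed, the front's crossing time);
- an arming latch: after an update, a new one is allowed only once the
  overlap has emptied — i.e. only when a wave *newly enters* the bump
  region. Without the latch the trailing edge of the same front
  re-triggers as soon as R expires (crossing takes slightly longer than
  R) and drags the bump back where it came from.

The gain/hold calibration moves the bump 4 cells per wavefront, within
the model's own bound of half a bump width per incoming wave. Smaller
displacements double the hop count relative to the BFS oracle in straight
corridors (the bump would visit every cell while one oracle hop covers
two). A run terminates as `arrived` when the bump center is within
arrival_radius = 6 cells (≈ half a bump diameter) of the target, whose
extended bump cannot center exactly on the stimulated node; budgets
default to max_steps = 8000 ms.

## Mazes

Obstacle masks are parametrized generators, not pixel copies of any
particular figure: `s_maze` (two interleaved walls forcing an S-shaped
corridor), `blocks` (a central and an offset rectangular block), and
`fine_structure` (a comb labyrinth with alternating gaps). All walls are
at least 2 cells thick: with interaction range 2, an edge may span two
free cells flanking a 1-cell wall, which would let both the waves and the
BFS oracle tunnel. Every generator validates that start and target remain
mutually reachable. BFS path lengths from corner to corner order as
open (30) < blocks (36) < s_maze (58) < fine_structure (84), and arrival
times order identically; note an axis-aligned block field costs no extra
hops (a monotone staircase skirts it), yet the traced path and arrival
time still grow because the bump must physically detour.

## Heterogeneous configuration

Per-neuron draws r_e, r_i ~ U[0,1]: excitatory c = −65 + 15 r_e²,
d = 8 − 6 r_e² (regular spiking → chattering, biased toward RS by the
square), inhibitory a = 0.02 + 0.08 r_i, b = 0.25 − 0.05 r_i
(low-threshold → fast spiking); plus independent ±10 % multiplicative
jitter on every nonzero synaptic weight. Heterogeneous wavefronts are
ragged and roughly twice as active (coexisting front generations), so the
overlap-centroid direction estimate is noisy; the bump still reaches the
target in 9 of the 10 test seeds on the blocks maze within the 8000 ms
budget, and the waves always traverse the entire free grid. The failing
seed wanders — its direction estimates are near-random even though its
wave field is intact — which we report as-is rather than filtering.

## What the simulations do and do not show

All experiments run on planar grids with single-neuron state encoding and
*given* maps; learning the map, non-grid manifolds, multi-neuron codes,
conductance synapses, plasticity and delays are out of scope. The
deterministic homogeneous setup is a numerical idealization: its perfect
four-fold symmetry (the spike raster is exactly invariant under 90°
rotation about the stimulated node) is what the heterogeneous suite
deliberately breaks. Success on these synthetic grids shows the
wave/bump mechanism is sound and robust to parameter dispersion; it does
not by itself show the mechanism scales to the connectivity statistics of
real tissue.

## Problem sizes and determinism

Default experiments use the 41×41 grid (1681 nodes per population; the
wave demo uses 101×101). A full planning run simulates 300–1300 ms of
model time in a few seconds of wall time; the complete acceptance
recomputation (`scripts/acceptance.py`) takes a few minutes on one CPU.
Homogeneous runs contain no randomness at all — outputs are byte-identical
across repetitions; heterogeneous runs are reproducible given the seed.
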