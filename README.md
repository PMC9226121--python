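# wavenav

Neural path planning with traveling waves and a continuous-attractor bump.

Many cognitive tasks — a rodent navigating a maze, an arm moving between
postures — can be cast as finding a short path through a *cognitive map*: a
graph in which each neuron encodes one point of a task-relevant manifold
and recurrent synapses encode adjacency. `wavenav` implements a two-layer
neural network that solves such graph-traversal problems directly in its
dynamics, with no external search algorithm:

- **Wave propagation layer (P).** Each grid node carries one excitatory
  (regular-spiking) and one inhibitory (fast-spiking) Izhikevich neuron,

  dv/dt = 0.04 v² + 5v + 140 − u + I,  du/dt = a(bv − u),
  with spike reset v ← c, u ← u + d at v ≥ 30 mV.

  Excitatory synapses decay as s(d) = s_max/d up to a cutoff range; the
  inhibitory partners suppress the wake of the front. Permanently
  stimulating the *target* node (DC current I = 25) makes it emit
  repeated, roughly circular wavefronts that sweep the free grid at about
  one cell per millisecond — a parallelized breadth-first search: the
  first-spike time of every neuron ranks it by BFS hop distance from the
  target (Spearman ρ ≈ 0.998).

- **Continuous attractor layer (C).** A rate-coded place-cell sheet with a
  shifted-Gaussian recurrent kernel,

  w(i,j) = J·exp(−‖(i−j)/N + Δ(t)‖²/σ²) − T,

  sustains a single bump of activity (≈11–12 neurons across) encoding the
  *current* state.

- **Coupling.** Whenever a wavefront newly enters the bump's active
  region, the direction vector Δ(t) = mean(C_t ∩ P_t) − p_t points from
  the bump center toward the overlap with the incoming front. Applied
  briefly inside the kernel, it shifts the bump a few cells toward the
  wave's origin; a recovery period R = 12 ms lets each front move the
  bump at most once. Wave by wave, the bump traces the incoming fronts
  back to their source — from start to target along a near-shortest path,
  around any obstacles.

Obstacles are static masks: blocked nodes have their wave-layer synapses
zeroed and their attractor activation clamped to zero.

## Worked example

```
$ wavenav run --preset s_maze --out out_smaze
status=arrived path_hops=65 arrival_time_ms=744 -> out_smaze/summary.json
```

The bump started at (2, 2) on a 41×41 grid whose two interleaved walls
force an S-shaped corridor, and reached the permanently stimulated target
(38, 38) after 744 simulated ms, changing its center 65 times. The BFS
oracle needs 58 hops on the same graph, so the traced path is within 13 %
of optimal (`"efficiency": 1.1207` in `summary.json`). `trajectory.csv`
holds the (t_ms, center_x, center_y) path; `raster.csv` the spike raster
of both wave-layer populations.

Other entry points:

```
$ wavenav bump-demo
bump center=(20, 20) diameter=11 cells peak=1.310 total=50.20

$ wavenav wave-demo --size 101 --duration 120
101x101 grid, 120 ms: speed=1.00 cells/ms spearman_rho=0.9997 raster -> wave_demo.csv

$ wavenav preset            # list named setups
$ wavenav validate --seed 1 # re-run the acceptance measurements
```

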