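# circtrack

Global data association for multi-object tracking by **minimum-cost
circulation**.

`circtrack` links per-frame point detections (cells, particles, vehicles)
into identity-preserving trajectories. It targets the tracking-by-detection
setting where detections are given and the open question is *which detection
belongs to which object* — including how many objects there are, which
detections are false positives, and where objects appear, disappear, or go
briefly undetected.

## The model

Given detections `x_1 … x_D`, a trajectory hypothesis is a set of disjoint
temporally-ordered chains. The MAP estimate over hypotheses factorizes into
per-detection and pairwise terms and becomes an integer program over binary
link variables with costs

- `C_i = log(β_i / (1 − β_i))` — observation cost, where `β_i` is the
  probability that detection `i` is a false positive (negative when the
  detection is more likely real),
- `C_i^en = −log P_enter`, `C_i^ex = −log P_exit` — trajectory birth/death
  costs,
- `C_ij = −log p(d_ij)` — transition cost, with `p` the survival p-value of
  the displacement `d_ij` under an empirical distribution of true
  inter-frame displacements; links spanning `g > 1` frames ("jumps", for
  occlusion or missed detection) pay an extra `−log p_jump`.

Each detection becomes a pre-node `o_i` and post-node `h_i`; a single dummy
node `s` closes every chain into a cycle `s → o_{k1} → h_{k1} → … → s`. On
this unit-capacity graph the MAP problem is exactly a **minimum-cost
circulation**: the optimal number of trajectories is the optimal circulation
amount, so no outer search over the object count is needed (unlike min-cost
*flow* formulations, which fix the flow value per solve).

The solver is a cost-scaling push/relabel algorithm whose flow pushes are
guided by a blocking flow (set-relabel toward deficit nodes), with price
refinement between scaling phases and optional arc fixing. Costs are
quantized to integers, so the termination threshold `ε < 1/n` certifies an
exactly optimal circulation. Independent reference solvers (exhaustive
enumeration, exact LP, successive shortest paths) certify the optimum on
small instances in the test suite.

## Worked example

```python
from circtrack import (SimulationConfig, simulate, CostConfig, track_once,
                       evaluate)

sim = SimulationConfig(n_objects_init=10, n_frames=30, arena=(120.0, 120.0),
                       speed_scale=1.0, miss_rate=0.1, noise_sigma=0.1,
                       min_separation=25.0, seed=4)
dets, gt = simulate(sim)
print(f"{len(dets)} detections over {dets.n_frames} frames")

cfg = CostConfig(use_gt_linkage=True, jump_window=2, p_jump=0.1)
solution, network, fitted = track_once(dets, cfg)
print(f"network: {network.n_nodes} nodes, {network.n_arcs} arcs")
print(f"estimated p_enter = {fitted.p_enter:.4f}, p_exit = {fitted.p_exit:.4f}")
print(f"{solution.flow_amount} trajectories, total cost {solution.total_cost:.2f}")

report = evaluate(solution, gt.ids, gt.frames, gt.positions, dets,
                  match_radius=3.0)
print(report)
```

prints

```
273 detections over 30 frames
network: 547 nodes, 2379 arcs
estimated p_enter = 0.0806, p_exit = 0.0806
14 trajectories, total cost -1060.39
MOTA   89.7%  MOTP   0.121  IDF1   85.9%  IDS    4  MT  90.0%  ML   0.0%  FAR   0.00
```

Ten objects drift through a 120×120 arena for 30 frames and 10% of their
footprints go undetected, leaving 273 detections. The pipeline estimates the
entry/exit rates from frame-count differences (0.0806), fits the
displacement distribution from adjacent-frame nearest-neighbor distances,
builds the circulation network and solves it. The 14 decoded trajectories
(10 objects, a few split where an object was invisible for more than the
2-frame jump window) cover 89.7% of ground-truth footprints net of errors
(MOTA), with localization error 0.12 px (MOTP), 4 identity switches, and 9
of 10 objects mostly tracked.

Iterative refinement (`iterate_tracking`) re-estimates each detection's
velocity from the previous solution, calibrates it with the median over its
four nearest neighbors, predicts gating positions, refits the displacement
distribution and rates, and penalizes jumps with the estimated jump
probability — which sharply reduces identity switches when per-frame
displacement is comparable to object spacing. A Frank–Wolfe harness
(`frank_wolfe`, step size `k/(k+2)`) extends the objective with quadratic
pairwise terms, solving a plain circulation per iteration.

There is also a CLI:

```bash
circtrack simulate --config cfg.yaml --out dets.csv --gt gt.csv
circtrack track --input dets.csv --config cfg.yaml --iters 3 \
    --out res.csv --gt gt.csv --radius 5
circtrack evaluate --pred res.csv --dets dets.csv --gt gt.csv --radius 5
circtrack solve --dimacs network.dmx --out flow.csv
```

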