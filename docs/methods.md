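# Methods

## Model

Identity inference over a recording is posed as a MAP problem with unary and
pairwise terms only. A hypothesis is a set of disjoint trajectories (no
splitting or merging); each detection is a Bernoulli observation with
false-positive probability `β_i`, and each trajectory is a Markov chain with
entry probability `P_enter`, per-link transition probabilities, and exit
probability `P_exit`. Taking negative logarithms gives an integer linear
program over binary variables `f_i` (detection used), `f_ij` (link),
`f_i^en`, `f_i^ex` (trajectory endpoints), with conservation constraints
tying them together.

The ILP is mapped to a minimum-cost circulation: detection `i` becomes a
pre-node `o_i` and post-node `h_i` with an observation arc `(o_i, h_i)` of
cost `C_i = log(β_i/(1−β_i))`; a single dummy node `s` carries an entry arc
`(s, o_i)` of cost `−log P_enter` and an exit arc `(h_i, s)` of cost
`−log P_exit`; every gated candidate pair gets a transition arc
`(h_i, o_j)` of cost `C_ij`. All capacities are one. Two structural facts
are load-bearing and are asserted at build time:

- transition arcs point strictly forward in time, so the graph minus `s` is
  a DAG and every cycle passes through `s` — a feasible circulation
  decomposes into arc-disjoint `s`-cycles, one per trajectory, and the
  circulation amount *is* the trajectory count;
- every node except `s` has a single in-arc or single out-arc
  (unit vertex capacity with one exception).

Minimizing circulation cost therefore solves the MAP problem with the
number of objects decided inside the optimization; no binary or incremental
search over the flow amount is needed.

## Solver

The solver is cost scaling with push/relabel, with pushes guided by a
blocking flow. A flow is ε-optimal under prices `p` if every residual arc
has reduced cost `c(v,w) + p(v) − p(w) ≥ −ε`. Starting from the zero
circulation (feasible by construction) and `ε = max |cost|`, each phase
halves ε, saturates all admissible arcs (residual, reduced cost < 0) —
producing an ε-optimal pseudo flow with node imbalances — and RESTOREs
feasibility by alternating:

1. **set-relabel** — repeatedly add ε to the prices of all nodes from which
   a deficit node is reachable in the admissible network, until every
   excess node has an admissible path to a deficit. Raising the whole
   reachable set preserves ε-optimality (any admissible arc entering the
   set would have put its tail in the set). The admissible arcs on
   excess→deficit paths form the blocking-flow marking.
2. **push/relabel** — push unit flows out of excess nodes, marked arcs
   first, at most `m` pushes per pass so each alternation makes guaranteed
   progress toward a saturated excess→deficit path.

Between phases, price refinement checks whether the circulation is already
ε/2-optimal under adjusted prices: if the admissible network is acyclic,
integer node labels are sought by difference-constraint relaxation (up to
`⌈√n⌉` sweeps, giving up conservatively otherwise); on success only prices
change and ε halves without flow work.

Numerical choices:

- **Quantization.** Real costs are multiplied by `cost_scale` (default
  10⁶) and rounded half away from zero. The optimality certificate
  `ε < 1/n` is valid for integer costs only.
- **Internal scaling.** Quantized costs are further multiplied by `n + 1`
  and the initial ε is rounded up to a power of two. Every ε in the
  halving schedule is then an exact integer, ε/2 inside price refinement
  is integral whenever refinement runs (ε ≥ 2), and termination at ε = 1
  is equivalent to ε < 1/n on the unscaled integers. No floating-point ε
  comparison exists anywhere in the solver.
- **Relabel guard.** A stuck excess node (no admissible out-arc) is
  relabeled by exactly +ε only while it also has no admissible in-arc;
  otherwise it is deferred to the next set-relabel round. The guarded
  relabel provably preserves both ε-optimality and the acyclicity of the
  admissible network, which in turn guarantees passes cannot cycle; the
  unguarded +ε relabel can push admissible in-arcs below −ε. Termination
  is carried by set-relabel, which strictly raises prices whenever any
  excess node is cut off.
- **Arc fixing** (off by default): transition arcs whose reduced cost
  exceeds `fix_threshold · ε` and that carry no flow are dropped from the
  scan sets. Clipped arcs are rechecked at each phase start *and* inside
  every set-relabel round (a clipped arc may be the only route to a
  deficit); the final optimality check always runs over all arcs and
  resumes solving with everything active if a clipped arc was needed.
- **Bug traps.** A RESTORE exceeding `10·(n+m)` passes, a price decrease
  inside RESTORE, or terminal imbalance raises an internal error rather
  than returning silently degraded output.
- Ties between equal-cost optima are resolved by the fixed arc order
  (enter, observation, exit per detection, then transitions sorted by
  (i, gap, j)), making runs byte-reproducible.

Three independent reference routes certify the solver in the tests: (a)
exhaustive enumeration of association hypotheses (bounded by an estimated
hypothesis count; exponential in general), (b) the exact LP relaxation
(integral because the constraint matrix is a network matrix; solved by
HiGHS), and (c) successive shortest paths on the flow-network twin obtained
by splitting `s` into a source and sink. SSP's per-K optima are convex in
K, realizing the equivalence "circulation optimum = min over K of the
K-unit flow optimum" that the formulation removes the search for.

## Cost estimation

- The displacement distribution is the empirical distribution of
  adjacent-frame nearest-neighbor distances; the p-value of a candidate
  displacement `d` is the survival fraction (share of training distances
  ≥ d), so the smallest displacements cost 0 and probabilities are clamped
  to `p_min` (default 1e−9) to keep costs finite. This estimator assumes
  slow motion relative to spacing; when a detection's true successor is
  missed, its nearest-neighbor sample is an unrelated object and the
  distribution acquires a heavy contaminated tail (fraction ≈ miss rate).
- Entry/exit rates from per-frame counts: births = first frame's count
  plus all positive adjacent-frame increases, deaths = last frame's count
  plus all decreases, each divided by the total detection count.
  Simultaneous births and deaths within one frame pair cancel, biasing
  both rates low in that regime (kept as stated; the bias is noted, not
  corrected).
- When detections are trusted (e.g., they are ground truth, or a
  high-precision detector), `use_gt_linkage=True` replaces `C_i` with
  `−(C_en + C_ex)` so every singleton cycle costs exactly zero and no
  detection can be dropped by the optimum. With the default `β = 0.4`
  instead, the per-detection reward (−0.41) rarely beats median transition
  costs on sparse synthetic data and the empty solution is optimal — the
  gt-linkage design is the right one for the simulated studies here.

## Iterative refinement

Iteration 1 is the plain pipeline. Iterations ≥ 2:

1. **Instant velocity** per detection = displacement *from its previous
   linked detection* divided by the frame gap (first detection of a chain
   inherits its successor's velocity). The backward-looking convention is
   deliberate: defining velocity by the outgoing link would make the
   predicted next position coincide exactly with the previous iteration's
   successor — zero residual on possibly wrong links — so the iteration
   could never overrule an identity switch. Measured on crossing-object
   simulations, the forward convention leaves the switch count unchanged
   across iterations while the backward one collapses it.
2. **Calibration**: componentwise median over the detection and its four
   nearest same-frame neighbors. This presumes locally coherent motion
   (tissue-like flows); with independently moving objects the median
   replaces a correct velocity with unrelated neighbors' and destroys the
   feature. The synthetic generator therefore offers `velocity_groups`
   (shared headings) to emulate the coherent regime.
3. **Gating and costs**: candidates are the k nearest detections to the
   *predicted* position `x_i + v_i · gap`; the displacement ECDF is refit
   on prediction residuals `|x_j − (x_i + v_i·gap)|` over the previous
   solution's gap-1 links (raw displacements would assign p ≈ 1 to every
   nearby candidate and lose all discrimination); entry/exit rates refit
   as trajectories/detections; jumps get the penalty `−log p_jump` with
   `p_jump` = jumps/links of the previous solution.

## Synthetic data and study conditions

The generator emulates particle/cell recordings: point objects in a box
with reflective walls, Brownian or constant-velocity motion (optionally in
coherent streams), Poisson births, per-object deaths, Bernoulli missed
detections, Gaussian localization noise, and uniform Poisson false
positives. Sub-streams per concern make, e.g., false-positive injection
leave trajectories bit-identical. `min_separation` rejection-samples
starting positions so "well separated" holds by construction. It does not
emulate appearance features, cell division, correlated detector failures,
or in-focus/out-of-focus effects — passing tests show the association
machinery is correct under the stated motion/noise models, not that the
cost design is adequate for any particular microscope or detector.

Study sizes (chosen once as the package's standard validation suite):

- **Solver sweeps**: 200 seeded random instances — 150 at D ≤ ~12
  (enumeration tier) and 50 at D up to 200 (LP tier) — with β on both
  sides of ½, varied gating (knn 1–3), jump windows 1–2, and occasional
  gt-linkage costs.
- **Clean recovery**: 20 objects, 50 frames, 300×300 arena, Brownian
  speed 1.0, noise σ 0.1, min separation 50, gt-linkage costs, jump
  window 1 (nothing to bridge; window 1 also removes zero-cost ties in
  which a jump skips a middle detection whose singleton cover costs 0).
  Expected outcome: MOTA 100%, zero switches.
- **Jump-arc study**: as above but 30 frames, 100×100, miss rate 0.1;
  jump window 2 (p_jump 0.1) versus 1, 20 seeds.
- **Refinement study**: 25 objects, 15 frames, 50×50, constant velocity
  4.0 in 2 coherent streams, noise σ 0.1, 20 seeds, 5 iterations. The
  per-frame displacement (≈ 4) is comparable to the object spacing
  (≈ 10), the regime where distance-only linking shuffles identities and
  the velocity feature is informative.
- **Estimator recovery** (100 seeds): entry rate on a birth-only design
  (15 objects + Poisson(0.6) births/frame, 25 frames) against the
  analytic configured rate; jump probability on the ground-truth
  association of a well-separated recording with miss rate 0.12 against
  the analytic `m/(1+m)`. The estimators are evaluated on inputs with
  known structure; running them downstream of the tracker adds a small
  systematic bias (±0.01) from the contaminated displacement ECDF, which
  is a property of the pipeline, not of the estimators.

## Known limitations

- The solver is pure Python over adjacency lists: exact and reproducible,
  at interpreter speed (hundreds of detections in fractions of a second;
  not the millions the underlying algorithm supports in compiled form).
- CLEAR-MOT matching here is per-frame greedy nearest-within-radius with
  persistence preference (not Hungarian); IDF1 does use an optimal global
  assignment. Numbers are reproducible but can differ slightly from other
  toolkits' matchers.
- The β ← 1 − confidence mapping is a convention, off by default; the
  rate estimator's simultaneous-birth/death undercount is kept as
  designed.
- Frank–Wolfe returns the fractional iterate plus an integral rounding
  from one final linearized solve; no approximation guarantee is claimed
  for nonconvex quadratics.
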