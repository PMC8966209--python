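"""Independent reference solvers used to certify the main solver.

Three routes to the optimum exist on small instances:

* exhaustive enumeration of every association hypothesis (tiny instances);
* the exact LP relaxation of the ILP — integral here because network
  conservation constraints form a totally unimodular matrix;
* successive shortest paths (SSP) on the flow-network twin, augmenting one
  unit of flow along the current cheapest s-t path per iteration and
  stopping when augmenting no longer decreases the cost.  Because SSP
  yields the optimal flow of value K after K augmentations, it also
  realizes the flow-vs-circulation equivalence: the circulation optimum is
  the minimum over K of the K-unit flow optimum.

All reference costs are on the quantized integer scale, so agreement with
the main solver is exact.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
from scipy.optimize import linprog
from scipy.sparse import coo_matrix

from .network import CirculationNetwork, build_flow_network

__all__ = [
    "OracleResult",
    "brute_force_solve",
    "ssp_solve",
    "flow_optima_by_K",
    "random_instance",
]

ENUM_MAX_D = 15
LP_MAX_D = 200


@dataclass
class OracleResult:
    optimal_cost: int
    optimal_K: int
    arc_flow: Optional[np.ndarray] = None  # one optimal binary arc set
    costs_by_K: Optional[List[int]] = None  # SSP: flow optimum per K


def _enumerate_hypotheses(net: CirculationNetwork) -> Tuple[int, int]:
    """Exhaustive search over association hypotheses.

    Detections are processed in index order (temporal order within the
    network's DAG); each is either skipped, starts a trajectory, or extends
    an open (successor-free) used detection along an existing transition
    arc.  Returns (optimal integer cost, optimal K).
    """
    D = net.n_detections
    enter = np.zeros(D, dtype=np.int64)
    obs = np.zeros(D, dtype=np.int64)
    exit_ = np.zeros(D, dtype=np.int64)
    trans: List[List[Tuple[int, int]]] = [[] for _ in range(D)]  # j -> [(i, cost)]
    for a in net.arcs:
        if a.kind == "enter":
            enter[a.det_pair[0]] = a.cost_int
        elif a.kind == "observation":
            obs[a.det_pair[0]] = a.cost_int
        elif a.kind == "exit":
            exit_[a.det_pair[0]] = a.cost_int
        else:
            i, j = a.det_pair
            trans[j].append((i, a.cost_int))

    best = [0, 0]  # cost, K of best hypothesis (empty = 0)

    def rec(j: int, open_set: frozenset, cost: int, k: int) -> None:
        if j == D:
            if cost < best[0]:
                best[0], best[1] = cost, k
            return
        # skip j
        rec(j + 1, open_set, cost, k)
        # start a new trajectory at j
        rec(j + 1, open_set | {j},
            cost + enter[j] + obs[j] + exit_[j], k + 1)
        # extend an open trajectory ending at i
        for i, c in trans[j]:
            if i in open_set:
                rec(j + 1, (open_set - {i}) | {j},
                    cost + obs[j] + c + exit_[j] - exit_[i], k)

    rec(0, frozenset(), 0, 0)
    return best[0], best[1]


def _lp_solve(net: CirculationNetwork) -> Tuple[int, np.ndarray]:
    """Exact LP over the circulation polytope; the constraint matrix is a
    network (totally unimodular) matrix, so the LP optimum is integral."""
    m = net.n_arcs
    c = net.int_costs().astype(float)
    rows, cols, vals = [], [], []
    for k, a in enumerate(net.arcs):
        rows.append(a.tail); cols.append(k); vals.append(1.0)
        rows.append(a.head); cols.append(k); vals.append(-1.0)
    A = coo_matrix((vals, (rows, cols)), shape=(net.n_nodes, m))
    res = linprog(c, A_eq=A, b_eq=np.zeros(net.n_nodes),
                  bounds=(0, 1), method="highs")
    if not res.success:
        raise RuntimeError(f"LP oracle failed: {res.message}")
    f = np.asarray(res.x)
    if np.abs(f - np.round(f)).max() > 1e-6:
        raise RuntimeError("LP relaxation returned a fractional optimum")
    f = np.round(f).astype(np.int64)
    return int(np.dot(net.int_costs(), f)), f


def brute_force_solve(net: CirculationNetwork) -> OracleResult:
    """Exact minimum-cost circulation by enumeration and/or exact LP.

    Enumeration runs for D <= 15 and the LP for D <= 200; where both run,
    their agreement is asserted.  Larger instances are refused.
    """
    D = net.n_detections
    if D > LP_MAX_D:
        raise ValueError(f"instance too large for the reference solver (D={D})")
    lp_cost, lp_flow = _lp_solve(net)
    K = int(sum(lp_flow[k] for k, a in enumerate(net.arcs) if a.kind == "enter"))
    indeg = np.zeros(max(D, 1))
    for a in net.arcs:
        if a.kind == "transition":
            indeg[a.det_pair[1]] += 1
    n_hypotheses = float(np.prod(2 + indeg[:D])) if D else 1.0
    if D <= ENUM_MAX_D and n_hypotheses <= 5e5:
        enum_cost, enum_K = _enumerate_hypotheses(net)
        if enum_cost != lp_cost:
            raise RuntimeError(
                f"oracle disagreement: enumeration {enum_cost} vs LP {lp_cost}"
            )
    return OracleResult(lp_cost, K, lp_flow)


def _ssp_residual(net: CirculationNetwork):
    """Residual arrays for the flow-network twin (source s, sink t)."""
    fn = build_flow_network(net, 0)
    n = fn.n_nodes
    m = len(fn.arcs)
    head = np.empty(2 * m, dtype=np.int64)
    cost = np.empty(2 * m, dtype=np.int64)
    resid = np.empty(2 * m, dtype=np.int64)
    out: List[List[int]] = [[] for _ in range(n)]
    for k, a in enumerate(fn.arcs):
        head[2 * k], head[2 * k + 1] = a.head, a.tail
        cost[2 * k], cost[2 * k + 1] = a.cost_int, -a.cost_int
        resid[2 * k], resid[2 * k + 1] = 1, 0
        out[a.tail].append(2 * k)
        out[a.head].append(2 * k + 1)
    return fn, n, m, head, cost, resid, out


def ssp_solve(net: CirculationNetwork) -> OracleResult:
    """Successive shortest paths with Bellman–Ford potentials then
    reduced-cost Dijkstra; augments K = 0, 1, 2, … one unit at a time and
    stops when the cheapest augmenting path no longer decreases the cost."""
    if net.n_detections == 0:
        return OracleResult(0, 0, np.zeros(0, dtype=np.int64), [0])
    fn, n, m, head, cost, resid, out = _ssp_residual(net)
    s, t = fn.source, fn.sink
    tails = np.empty(2 * m, dtype=np.int64)
    for v in range(n):
        for a in out[v]:
            tails[a] = v
    # Bellman-Ford potentials from s over the initial residual graph
    INF = float("inf")
    pot = np.full(n, 0.0)
    dist = np.full(n, INF)
    dist[s] = 0.0
    for _ in range(n):
        changed = False
        for a in range(2 * m):
            if resid[a] <= 0:
                continue
            v, w = tails[a], head[a]
            if dist[v] + cost[a] < dist[w]:
                dist[w] = dist[v] + cost[a]
                changed = True
        if not changed:
            break
    else:
        raise RuntimeError("negative cycle in the initial residual graph")
    pot = np.where(np.isfinite(dist), dist, 0.0)

    costs_by_K = [0]
    total = 0
    while True:
        # Dijkstra with reduced costs
        dist = np.full(n, INF)
        dist[s] = 0.0
        prev_arc = np.full(n, -1, dtype=np.int64)
        pq = [(0.0, s)]
        done = np.zeros(n, dtype=bool)
        while pq:
            d, v = heapq.heappop(pq)
            if done[v]:
                continue
            done[v] = True
            for a in out[v]:
                if resid[a] <= 0:
                    continue
                w = head[a]
                rc = cost[a] + pot[v] - pot[w]
                nd = d + rc
                if nd < dist[w] - 1e-9:
                    dist[w] = nd
                    prev_arc[w] = a
                    heapq.heappush(pq, (nd, w))
        if not np.isfinite(dist[t]):
            break
        path_cost = int(round(dist[t] - pot[s] + pot[t]))
        if path_cost >= 0:
            break
        # augment one unit along the shortest path
        v = t
        while v != s:
            a = int(prev_arc[v])
            resid[a] -= 1
            resid[a ^ 1] += 1
            v = int(tails[a])
        total += path_cost
        costs_by_K.append(total)
        pot = np.where(np.isfinite(dist), pot + dist, pot)
    K = len(costs_by_K) - 1
    flow = (1 - resid[0::2]).astype(np.int64)
    return OracleResult(total, K, flow, costs_by_K)


def flow_optima_by_K(net: CirculationNetwork, K_max: Optional[int] = None) -> List[int]:
    """Optimal K-unit flow cost on the flow-network twin for K = 0..K_max
    (continuing past the point where augmenting stops paying off), for the
    flow-vs-circulation equivalence check.  K beyond the maximum feasible
    flow is omitted."""
    if net.n_detections == 0:
        return [0]
    if K_max is None:
        K_max = net.n_detections
    fn, n, m, head, cost, resid, out = _ssp_residual(net)
    s, t = fn.source, fn.sink
    tails = np.empty(2 * m, dtype=np.int64)
    for v in range(n):
        for a in out[v]:
            tails[a] = v
    costs = [0]
    total = 0
    INF = float("inf")
    for _ in range(K_max):
        # Bellman-Ford (simple, exact, handles negatives after augmentation)
        dist = np.full(n, INF)
        dist[s] = 0.0
        prev_arc = np.full(n, -1, dtype=np.int64)
        for _ in range(n):
            changed = False
            for a in range(2 * m):
                if resid[a] <= 0:
                    continue
                v, w = tails[a], head[a]
                if np.isfinite(dist[v]) and dist[v] + cost[a] < dist[w]:
                    dist[w] = dist[v] + cost[a]
                    prev_arc[w] = a
                    changed = True
            if not changed:
                break
        if not np.isfinite(dist[t]):
            break
        v = t
        while v != s:
            a = int(prev_arc[v])
            resid[a] -= 1
            resid[a ^ 1] += 1
            v = int(tails[a])
        total += int(dist[t])
        costs.append(total)
    return costs


def random_instance(seed: int, tier: str = "small") -> Optional[CirculationNetwork]:
    """A seeded random tracking network for validation sweeps.

    Draws a small simulated recording, per-detection false-positive
    probabilities on both sides of 1/2 (so observation costs take both
    signs), random entry/exit rates, gating breadth, jump window and,
    occasionally, the ground-truth linkage cost design.  ``tier``
    controls the problem size: "small" keeps D low enough for the
    enumeration oracle, "medium" for the exact-LP oracle.  Returns None
    when the draw produced no detections.
    """
    from .costs import CostConfig, fit_distance_ecdf, gate_candidates
    from .network import build_circulation_network
    from .synthetic import SimulationConfig, nn_distance_samples, simulate

    rng = np.random.default_rng(seed)
    if tier == "small":
        n_obj = int(rng.integers(1, 4))
        n_frames = int(rng.integers(2, 5))
        arena = (25.0, 25.0)
    elif tier == "medium":
        n_obj = int(rng.integers(10, 20))
        n_frames = int(rng.integers(5, 9))
        arena = (60.0, 60.0)
    else:
        raise ValueError(f"unknown tier {tier!r}")
    sim = SimulationConfig(
        n_objects_init=n_obj,
        n_frames=n_frames,
        arena=arena,
        speed_scale=float(rng.uniform(0.5, 3.0)),
        miss_rate=float(rng.uniform(0, 0.3)),
        fp_rate=float(rng.uniform(0, 1.5)),
        birth_rate=float(rng.uniform(0, 0.5)),
        death_rate=float(rng.uniform(0, 0.1)),
        seed=int(rng.integers(0, 2**31)),
    )
    dets, _ = simulate(sim)
    if len(dets) == 0 or len(dets) > LP_MAX_D:
        return None
    for d in dets.detections:
        d.beta = float(rng.uniform(0.05, 0.95))
    cfg = CostConfig(
        p_enter=float(rng.uniform(0.05, 0.9)),
        p_exit=float(rng.uniform(0.05, 0.9)),
        knn=int(rng.integers(1, 4)),
        jump_window=int(rng.integers(1, 3)),
        p_jump=float(rng.uniform(0.05, 1.0)),
        use_gt_linkage=bool(rng.random() < 0.3),
    )
    cands = gate_candidates(dets, cfg.knn, cfg.jump_window)
    samples = nn_distance_samples(dets)
    ecdf = fit_distance_ecdf(samples if samples.size else np.array([1.0]))
    return build_circulation_network(dets, cfg, cands, ecdf)
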