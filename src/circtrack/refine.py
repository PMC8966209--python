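"""Iterative tracking refinement and the Frank–Wolfe harness.

One-shot tracking links detections by raw inter-detection distance.  With
a first set of trajectory hypotheses in hand, two things improve:

* motion: each detection gets an instant velocity from its link in the
  previous solution, calibrated by the component-wise median over itself
  and its four nearest same-frame neighbors; gating and transition costs
  then use the distance between the *predicted* position (x + v·gap) and
  the candidate;
* parameters: the entry/exit rates and the displacement distribution are
  refit from the previous solution, and the jump probability ``p_jump``
  (jumps / all links) penalizes gap > 1 arcs by an extra ``-log p_jump``.

Iterating this loop typically removes identity switches caused by the
velocity-blind first pass.

The Frank–Wolfe harness extends the linear objective with a quadratic
(pairwise) term over arc variables: each iteration solves the linearized
subproblem (a plain minimum-cost circulation under gradient costs) and
steps with γ_k = k/(k+2); the iterate stays a convex combination of
feasible circulations, and a final linearized solve rounds it to an
integral circulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .costs import (
    CostConfig,
    DistanceECDF,
    estimate_rates_from_counts,
    fit_distance_ecdf,
    gate_candidates,
)
from .detections import DetectionSet
from .network import CirculationNetwork, build_circulation_network
from .solver import solve
from .synthetic import nn_distance_samples
from .trajectories import Solution, flow_to_trajectories

__all__ = [
    "IterationState",
    "QuadraticObjective",
    "track_once",
    "estimate_velocities",
    "smooth_velocities",
    "estimate_p_jump",
    "iterate_tracking",
    "frank_wolfe",
]


@dataclass
class IterationState:
    """Snapshot of one refinement iteration."""

    iteration: int
    solution: Solution
    config: CostConfig
    velocities: Optional[np.ndarray] = None
    p_jump: Optional[float] = None


def track_once(
    dets: DetectionSet,
    config: Optional[CostConfig] = None,
    ecdf: Optional[DistanceECDF] = None,
    estimate_rates: bool = True,
) -> Tuple[Solution, CirculationNetwork, CostConfig]:
    """The plain (non-iterative) pipeline: fit the displacement ECDF from
    adjacent-frame nearest-neighbor distances, estimate entry/exit rates
    from frame-count differences, gate, build the network, solve, decode."""
    if config is None:
        config = CostConfig()
    if len(dets) == 0:
        return Solution([], 0.0, 0), CirculationNetwork(0, [], config.cost_scale if config else 1), config
    if estimate_rates and dets.n_frames >= 2:
        p_enter, p_exit = estimate_rates_from_counts(dets.frame_counts(), config.p_min)
        cfg = CostConfig(**{**config.to_dict(), "p_enter": p_enter, "p_exit": p_exit})
    else:
        cfg = config
    if ecdf is None:
        samples = nn_distance_samples(dets)
        if samples.size == 0:
            samples = np.array([1.0])
        ecdf = fit_distance_ecdf(samples)
    if cfg.jump_window > 1 and cfg.p_jump is None:
        cfg = CostConfig(**{**cfg.to_dict(), "p_jump": 1.0})
    cands = gate_candidates(dets, cfg.knn, cfg.jump_window)
    net = build_circulation_network(dets, cfg, cands, ecdf)
    flow, _, _ = solve(net)
    return flow_to_trajectories(net, flow, dets), net, cfg


def estimate_velocities(solution: Solution, dets: DetectionSet) -> np.ndarray:
    """Instant velocity per detection: the incoming displacement, i.e. the
    displacement from the previous linked detection divided by the frame
    gap.  The first detection of a trajectory inherits its successor's
    velocity; unlinked detections get zero.

    The backward-looking convention matters: predicting a detection's next
    location must not use the outgoing link of the previous iteration's
    solution, or the prediction would simply reproduce that link (including
    its identity switches) with zero residual.  The incoming displacement
    is the causal motion estimate that lets the next iteration overrule a
    bad link.
    """
    v = np.zeros((len(dets), dets.dim))
    for traj in solution.trajectories:
        chain = traj.detections
        for i, j in zip(chain[:-1], chain[1:]):
            gap = dets[j].frame - dets[i].frame
            v[j] = (dets[j].position - dets[i].position) / gap
        if len(chain) >= 2:
            v[chain[0]] = v[chain[1]]
    return v


def smooth_velocities(velocities: np.ndarray, dets: DetectionSet, k: int = 4) -> np.ndarray:
    """Calibrate each detection's velocity by the component-wise median over
    itself and its ``k`` nearest same-frame neighbors (all available when a
    frame holds fewer than k+1 detections)."""
    velocities = np.asarray(velocities, dtype=float)
    out = velocities.copy()
    positions = dets.positions()
    for group in dets.by_frame():
        if len(group) < 2:
            continue
        idx = np.asarray(group)
        pos = positions[idx]
        for local, di in enumerate(idx):
            d = np.linalg.norm(pos - pos[local], axis=1)
            order = np.lexsort((idx, d))
            take = idx[order[: k + 1]]  # self is at distance 0
            out[di] = np.median(velocities[take], axis=0)
    return out


def estimate_p_jump(solution: Solution, dets: DetectionSet, p_min: float = 1e-9) -> float:
    """Fraction of links spanning more than one frame, clamped to
    (p_min, 1]; returns p_min when the solution has no links."""
    links = solution.links()
    if not links:
        return p_min
    jumps = sum(1 for i, j in links if dets[j].frame - dets[i].frame > 1)
    return min(max(jumps / len(links), p_min), 1.0)


def _refit_from_solution(
    solution: Solution, dets: DetectionSet, config: CostConfig,
    velocities: Optional[np.ndarray] = None,
    gap1_only: bool = True,
) -> Tuple[DistanceECDF, float, float]:
    """Refit the displacement ECDF and entry/exit rates from a solution.

    When velocities are given, the ECDF is fitted on prediction residuals
    ``|x_j - (x_i + v_i * gap)|`` over the previous solution's links — the
    same quantity the next iteration's transition costs are computed from —
    otherwise on raw linked displacements.
    """
    dists = []
    for i, j in solution.links():
        gap = dets[j].frame - dets[i].frame
        if gap1_only and gap != 1:
            continue
        if velocities is None:
            ref = dets[i].position
        else:
            ref = dets[i].position + velocities[i] * gap
        dists.append(float(np.linalg.norm(dets[j].position - ref)))
    if not dists:
        dists = list(nn_distance_samples(dets)) or [1.0]
    ecdf = fit_distance_ecdf(np.asarray(dists))
    total = sum(len(t) for t in solution.trajectories)
    K = solution.flow_amount
    if total > 0:
        rate = min(max(K / total, config.p_min), 1.0)
        p_enter = p_exit = rate
    else:
        p_enter, p_exit = config.p_enter, config.p_exit
    return ecdf, p_enter, p_exit


def iterate_tracking(
    dets: DetectionSet,
    config: Optional[CostConfig] = None,
    n_iterations: int = 1,
    refit_ecdf: bool = True,
    refit_rates: bool = True,
    refit_p_jump: bool = True,
    use_velocity: bool = True,
) -> List[IterationState]:
    """The iterative refinement loop.

    Iteration 1 is the plain pipeline (position-based gating).  Iterations
    >= 2 rebuild all costs using velocity-predicted gating distances, the
    jump penalty -log(p·p_jump), and rates/ECDF refit from the previous
    solution.  With every refinement switched off, later iterations rebuild
    the identical network and reproduce the plain pipeline exactly.
    Returns the per-iteration states in order.
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    solution, net, cfg = track_once(dets, config)
    states = [IterationState(1, solution, cfg)]
    for it in range(2, n_iterations + 1):
        prev = states[-1].solution
        if use_velocity:
            vel = smooth_velocities(estimate_velocities(prev, dets), dets)
        else:
            vel = np.zeros((len(dets), dets.dim))
        if refit_p_jump:
            p_jump = estimate_p_jump(prev, dets, cfg.p_min)
        else:
            p_jump = cfg.p_jump
        if refit_ecdf or refit_rates:
            ecdf, p_enter, p_exit = _refit_from_solution(
                prev, dets, cfg, vel if use_velocity else None)
        if not refit_rates:
            p_enter, p_exit = cfg.p_enter, cfg.p_exit
        if not refit_ecdf:
            samples = nn_distance_samples(dets)
            ecdf = fit_distance_ecdf(samples if samples.size else np.array([1.0]))
        it_cfg = CostConfig(**{
            **cfg.to_dict(),
            "p_enter": p_enter, "p_exit": p_exit, "p_jump": p_jump,
        })
        # gate on predicted positions; transition distance for a gap-g
        # candidate is measured from x_i + v_i * g
        cands = []
        positions = dets.positions()
        for gap in range(1, it_cfg.jump_window + 1):
            predicted = positions + vel * gap
            for i, j, d, g in gate_candidates(dets, it_cfg.knn, it_cfg.jump_window,
                                              predicted_positions=predicted):
                if g == gap:
                    cands.append((i, j, d, g))
        seen = {}
        for i, j, d, g in cands:  # dedupe (keep smallest distance)
            key = (i, j)
            if key not in seen or d < seen[key][2]:
                seen[key] = (i, j, d, g)
        cands = sorted(seen.values(), key=lambda t: (t[0], t[3], t[1]))
        net = build_circulation_network(dets, it_cfg, cands, ecdf)
        flow, _, _ = solve(net)
        sol = flow_to_trajectories(net, flow, dets)
        states.append(IterationState(it, sol, it_cfg, vel, p_jump))
    return states


@dataclass
class QuadraticObjective:
    """Objective ``c·x + x'Qx/2`` over the network's forward-arc variables;
    Q is given as a dense or sparse symmetric matrix."""

    linear: np.ndarray
    quadratic: np.ndarray

    def __post_init__(self) -> None:
        self.linear = np.asarray(self.linear, dtype=float)
        self.quadratic = np.asarray(self.quadratic, dtype=float)
        m = self.linear.shape[0]
        if self.quadratic.shape != (m, m):
            raise ValueError("quadratic part must be m x m")
        if not np.allclose(self.quadratic, self.quadratic.T):
            raise ValueError("quadratic part must be symmetric")

    def value(self, x: np.ndarray) -> float:
        return float(self.linear @ x + 0.5 * x @ self.quadratic @ x)

    def gradient(self, x: np.ndarray) -> np.ndarray:
        return self.linear + self.quadratic @ x


def frank_wolfe(
    obj: QuadraticObjective,
    net: CirculationNetwork,
    n_iterations: int = 10,
) -> Tuple[np.ndarray, np.ndarray, List[float], List[float]]:
    """Frank–Wolfe over the circulation polytope with step size k/(k+2).

    Starts from the zero circulation.  At iteration k the gradient is
    mapped to arc costs, the linearized subproblem is solved exactly by the
    circulation solver, and ``x ← x + γ_k (v - x)`` with ``γ_k = k/(k+2)``.
    Returns ``(x, x_integral, objective_trace, step_sizes)`` where
    ``x_integral`` comes from one final linearized solve at the last
    iterate.
    """
    m = net.n_arcs
    if obj.linear.shape[0] != m:
        raise ValueError("objective dimension must match the arc count")
    x = np.zeros(m)
    trace = [obj.value(x)]
    gammas = []
    for k in range(1, n_iterations + 1):
        grad = obj.gradient(x)
        v, _, _ = solve(net.with_costs(grad))
        gamma = k / (k + 2)
        gammas.append(gamma)
        x = x + gamma * (v - x)
        trace.append(obj.value(x))
    v, _, _ = solve(net.with_costs(obj.gradient(x)))
    return x, v.astype(np.int64), trace, gammas
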