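"""Blocking-flow-guided cost-scaling minimum-cost circulation solver.

The solver refines an ε-optimal circulation to an ε/2-optimal one per phase
(ε-optimality: every residual arc has reduced cost ``c(v,w)+p(v)-p(w) >=
-ε``), starting from the zero circulation with ε equal to the largest
absolute arc cost and stopping once ε is small enough that ε-optimality
certifies exact optimality for integer costs.

Each phase saturates all admissible arcs (residual arcs with negative
reduced cost), producing an ε-optimal *pseudo* flow with node imbalances,
then RESTOREs feasibility by alternating two steps:

* ``set_relabel`` — repeatedly raises by ε the prices of all nodes from
  which a deficit node is reachable in the admissible network, until every
  excess node has an admissible path to a deficit; the admissible arcs on
  those excess→deficit paths form the blocking-flow guidance;
* ``push_relabel_pass`` — pushes unit flows out of excess nodes, marked
  (blocking) arcs first, relabeling a node by +ε only when it has excess
  and no admissible out-arc; a pass stops after ``m`` pushes so each
  set-relabel/push alternation makes guaranteed progress.

Between phases, price refinement tries to halve ε by adjusting prices only,
which is possible when the admissible network is acyclic.

Integer arithmetic: quantized arc costs are internally multiplied by
``n + 1`` and the initial ε is rounded up to a power of two, so every ε in
the halving schedule is an exact integer and termination at ε = 1 is
equivalent to ε < 1/n on the unscaled integers, certifying optimality.
Optional arc fixing removes transition arcs with large positive reduced
cost from the scan sets; they are rechecked at every phase start and the
final optimality check always runs over all arcs.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

from .network import CirculationNetwork

__all__ = ["SolverState", "solve", "check_eps_optimality"]


class SolverError(RuntimeError):
    """Internal invariant violated (bug trap, not a user error)."""


@dataclass
class SolverStats:
    pushes: int = 0
    relabels: int = 0
    set_relabel_rounds: int = 0
    phases: int = 0
    pr_successes: int = 0
    pr_giveups: int = 0
    restore_passes: int = 0
    max_pushes_per_pass: int = 0
    phase_log: List[dict] = field(default_factory=list)


class SolverState:
    """Mutable state of the cost-scaling circulation algorithm.

    Residual arcs are stored in pairs: residual arc ``2k`` is forward arc
    ``k`` of the network, arc ``2k+1`` its reverse (cost negated, capacity
    0).  ``resid[a]`` is the residual capacity; the flow on forward arc
    ``k`` is ``1 - resid[2k]``.
    """

    def __init__(
        self,
        net: CirculationNetwork,
        fix_threshold: Optional[float] = None,
        restore_cap_factor: int = 10,
    ):
        self.net = net
        self.n = net.n_nodes
        self.m = net.n_arcs
        self.alpha = self.n + 1  # internal cost scale: ε=1 certifies optimality
        cost_int = net.int_costs()
        internal = cost_int * self.alpha
        self.cost = np.empty(2 * self.m, dtype=np.int64)
        self.cost[0::2] = internal
        self.cost[1::2] = -internal
        self.head = np.empty(2 * self.m, dtype=np.int64)
        self.tail = np.empty(2 * self.m, dtype=np.int64)
        for k, a in enumerate(net.arcs):
            self.head[2 * k], self.tail[2 * k] = a.head, a.tail
            self.head[2 * k + 1], self.tail[2 * k + 1] = a.tail, a.head
        self.resid = np.empty(2 * self.m, dtype=np.int64)
        self.resid[0::2] = 1
        self.resid[1::2] = 0
        self.out_arcs: List[List[int]] = [[] for _ in range(self.n)]
        for a in range(2 * self.m):
            self.out_arcs[self.tail[a]].append(a)
        self.price = np.zeros(self.n, dtype=np.int64)
        self.excess = np.zeros(self.n, dtype=np.int64)
        C = int(np.abs(internal).max()) if self.m else 0
        self.eps0 = 1 << max(int(C - 1).bit_length(), 0) if C > 0 else 1
        self.epsilon = self.eps0
        self.push_cap = max(self.m, 1)
        self.delta = int(np.ceil(np.sqrt(self.n)))  # diagnostic tuning constant
        self.pr_cap = int(np.ceil(np.sqrt(self.n)))
        self.restore_cap = restore_cap_factor * (self.n + self.m) + 10
        self.fix_threshold = fix_threshold
        self.active = np.ones(self.m, dtype=bool)
        self.stats = SolverStats()

    # ------------------------------------------------------------------ #
    def reduced_cost(self, a: int) -> int:
        return int(self.cost[a] + self.price[self.tail[a]] - self.price[self.head[a]])

    def _arc_active(self, a: int) -> bool:
        return bool(self.active[a >> 1])

    def flow(self) -> np.ndarray:
        """Binary flow on forward arcs."""
        return (1 - self.resid[0::2]).astype(np.int64)

    def total_cost_int(self) -> int:
        """Total circulation cost in quantized (cost_int) units."""
        return int(np.dot(self.net.int_costs(), self.flow()))

    def total_cost_real(self) -> float:
        return float(np.dot(self.net.real_costs(), self.flow()))

    def total_excess(self) -> int:
        return int(self.excess[self.excess > 0].sum())

    # ------------------------------------------------------------------ #
    def check_eps_optimality(self, eps: Optional[int] = None,
                             all_arcs: bool = True) -> bool:
        """True iff every residual arc has reduced cost >= -eps (internal
        units).  ``all_arcs=False`` restricts to the active (unfixed) set."""
        if eps is None:
            eps = self.epsilon
        p = self.price
        for a in range(2 * self.m):
            if self.resid[a] <= 0:
                continue
            if not all_arcs and not self._arc_active(a):
                continue
            if self.cost[a] + p[self.tail[a]] - p[self.head[a]] < -eps:
                return False
        return True

    def _violating_arcs(self, eps: int) -> List[int]:
        p = self.price
        return [
            a for a in range(2 * self.m)
            if self.resid[a] > 0
            and self.cost[a] + p[self.tail[a]] - p[self.head[a]] < -eps
        ]

    # ------------------------------------------------------------------ #
    def saturate_admissible(self) -> None:
        """Saturate every active admissible arc, making the flow an
        ε-optimal pseudo flow (imbalances recorded in ``excess``)."""
        p, cost, head, tail, resid = self.price, self.cost, self.head, self.tail, self.resid
        for a in range(2 * self.m):
            r = resid[a]
            if r <= 0 or not self.active[a >> 1]:
                continue
            if cost[a] + p[tail[a]] - p[head[a]] < 0:
                resid[a] = 0
                resid[a ^ 1] += r
                self.excess[tail[a]] -= r
                self.excess[head[a]] += r

    def _admissible_reach_sets(self) -> Tuple[np.ndarray, np.ndarray]:
        """(S, R): S = nodes from which a deficit is reachable in the
        admissible network; R = nodes reachable from an excess node."""
        p, cost, head, tail, resid = self.price, self.cost, self.head, self.tail, self.resid
        S = self.excess < 0
        queue = deque(np.flatnonzero(S))
        while queue:
            v = queue.popleft()
            for a in self.out_arcs[v]:
                b = a ^ 1  # arc into v
                u = head[a]  # = tail[b]
                if S[u] or resid[b] <= 0 or not self.active[b >> 1]:
                    continue
                if cost[b] + p[u] - p[v] < 0:
                    S[u] = True
                    queue.append(u)
        R = self.excess > 0
        queue = deque(np.flatnonzero(R))
        while queue:
            v = queue.popleft()
            for a in self.out_arcs[v]:
                w = head[a]
                if R[w] or resid[a] <= 0 or not self.active[a >> 1]:
                    continue
                if cost[a] + p[v] - p[w] < 0:
                    R[w] = True
                    queue.append(w)
        return S, R

    def set_relabel(self) -> np.ndarray:
        """Raise prices until every excess node has an admissible path to a
        deficit; return the blocking-direction marking (boolean per residual
        arc: admissible arcs lying on excess→deficit paths)."""
        eps = self.epsilon
        rounds = 0
        while True:
            if self.fix_threshold is not None:
                # a clipped arc may be the only route to a deficit; its
                # reduced cost falls as S is raised, so recheck each round
                self._recheck_fixed_arcs()
            S, R = self._admissible_reach_sets()
            excess_nodes = self.excess > 0
            if not excess_nodes.any() or (S[excess_nodes]).all():
                break
            if not S.any():  # every deficit is trivially in S; assert sanity
                raise SolverError("no deficit node while excess remains")
            self.price[S] += eps
            rounds += 1
            self.stats.set_relabel_rounds += 1
            if rounds > self.restore_cap:
                raise SolverError("set_relabel failed to connect excess to deficit")
        marked = np.zeros(2 * self.m, dtype=bool)
        p, cost, head, tail, resid = self.price, self.cost, self.head, self.tail, self.resid
        for a in range(2 * self.m):
            if resid[a] <= 0 or not self.active[a >> 1]:
                continue
            v, w = tail[a], head[a]
            if R[v] and S[w] and cost[a] + p[v] - p[w] < 0:
                marked[a] = True
        return marked

    def push_relabel_pass(self, marked: Optional[np.ndarray] = None) -> int:
        """Push unit flows out of excess nodes, marked (blocking) arcs
        first; relabel an excess node by +ε when it has no admissible
        out-arc.  Returns the number of pushes (capped at ``push_cap``).

        The relabel carries a safety guard: it is applied only while the
        node also has no admissible in-arc, which keeps ε-optimality and the
        acyclicity of the admissible network intact throughout RESTORE (the
        raised node's out-arcs stay non-admissible and its in-arcs stay
        >= -ε).  A node that stays stuck is deferred to the next set-relabel
        round, which repairs excess→deficit reachability globally.
        """
        if marked is None:
            marked = np.zeros(2 * self.m, dtype=bool)
        eps = self.epsilon
        p, cost, head, resid = self.price, self.cost, self.head, self.resid
        excess = self.excess
        pushes = 0
        queue = deque(int(v) for v in np.flatnonzero(excess > 0))
        in_queue = np.zeros(self.n, dtype=bool)
        in_queue[excess > 0] = True
        relabeled = np.zeros(self.n, dtype=bool)
        while queue and pushes < self.push_cap:
            v = queue.popleft()
            in_queue[v] = False
            while excess[v] > 0 and pushes < self.push_cap:
                best = -1
                for a in self.out_arcs[v]:
                    if resid[a] <= 0 or not self.active[a >> 1]:
                        continue
                    if cost[a] + p[v] - p[head[a]] < 0:
                        if marked[a]:
                            best = a
                            break
                        if best < 0:
                            best = a
                if best >= 0:
                    a = best
                    amt = min(int(excess[v]), int(resid[a]))
                    resid[a] -= amt
                    resid[a ^ 1] += amt
                    excess[v] -= amt
                    w = int(head[a])
                    excess[w] += amt
                    pushes += 1
                    self.stats.pushes += 1
                    if excess[w] > 0 and not in_queue[w]:
                        queue.append(w)
                        in_queue[w] = True
                    continue
                # no admissible out-arc: relabel if safe, else defer
                if relabeled[v]:
                    break
                has_adm_in = False
                for a in self.out_arcs[v]:
                    b = a ^ 1  # arc into v
                    if resid[b] <= 0 or not self.active[b >> 1]:
                        continue
                    if cost[b] + p[head[a]] - p[v] < 0:
                        has_adm_in = True
                        break
                if has_adm_in:
                    break
                p[v] += eps
                relabeled[v] = True
                self.stats.relabels += 1
        self.stats.max_pushes_per_pass = max(self.stats.max_pushes_per_pass, pushes)
        return pushes

    def restore(self) -> None:
        """Turn the ε-optimal pseudo flow into an ε-optimal feasible
        circulation by alternating set-relabel and guided push/relabel."""
        passes = 0
        price_before = self.price.copy()
        while self.total_excess() > 0:
            marked = self.set_relabel()
            self.push_relabel_pass(marked)
            passes += 1
            self.stats.restore_passes += 1
            if passes > self.restore_cap:
                raise SolverError(
                    f"RESTORE exceeded {self.restore_cap} passes "
                    f"(total excess {self.total_excess()})"
                )
        if (self.price < price_before).any():
            raise SolverError("prices decreased within RESTORE")

    # ------------------------------------------------------------------ #
    def _admissible_has_cycle(self) -> bool:
        """DFS cycle check on the admissible network."""
        p, cost, head, resid = self.price, self.cost, self.head, self.resid
        adm: List[List[int]] = [[] for _ in range(self.n)]
        for a in range(2 * self.m):
            if resid[a] > 0 and self.active[a >> 1] and \
                    cost[a] + p[self.tail[a]] - p[head[a]] < 0:
                adm[self.tail[a]].append(int(head[a]))
        color = np.zeros(self.n, dtype=np.int8)  # 0 white, 1 gray, 2 black
        for start in range(self.n):
            if color[start]:
                continue
            stack = [(start, iter(adm[start]))]
            color[start] = 1
            while stack:
                v, it = stack[-1]
                advanced = False
                for w in it:
                    if color[w] == 1:
                        return True
                    if color[w] == 0:
                        color[w] = 1
                        stack.append((w, iter(adm[w])))
                        advanced = True
                        break
                if not advanced:
                    color[v] = 2
                    stack.pop()
        return False

    def price_refinement(self) -> bool:
        """Try to make the current circulation ε/2-optimal by adjusting
        prices only.  Returns True on success (caller halves ε).  Gives up —
        without touching anything — if the admissible network has a cycle or
        the difference-constraint relaxation has not converged within
        ``pr_cap`` sweeps.  Never changes the flow or any node balance."""
        eps = self.epsilon
        if eps <= 1:
            return False
        if self._admissible_has_cycle():
            return False
        target = eps >> 1
        # Difference constraints: find integer labels mu with
        # mu(w) - mu(v) <= floor(c_p(a)/target) + 1 for every residual arc,
        # then p'(v) = p(v) + mu(v)*target gives c_p'(a) >= -target.
        p, cost, head, tail, resid = self.price, self.cost, self.head, self.tail, self.resid
        arcs = [a for a in range(2 * self.m) if resid[a] > 0 and self.active[a >> 1]]
        L = {
            a: (self.reduced_cost(a) // target) + 1  # floor for any sign
            for a in arcs
        }
        mu = np.zeros(self.n, dtype=np.int64)
        converged = False
        for _ in range(self.pr_cap):
            changed = False
            for a in arcs:
                cand = mu[tail[a]] + L[a]
                if cand < mu[head[a]]:
                    mu[head[a]] = cand
                    changed = True
            if not changed:
                converged = True
                break
        if not converged:
            self.stats.pr_giveups += 1
            return False
        self.price += mu * target
        if not self.check_eps_optimality(target, all_arcs=False):
            raise SolverError("price refinement produced a non-ε/2-optimal state")
        self.stats.pr_successes += 1
        return True

    # ------------------------------------------------------------------ #
    def _recheck_fixed_arcs(self) -> None:
        """Reactivate clipped transition arcs whose reduced cost fell back
        under the threshold; clip active flow-free transition arcs above it."""
        if self.fix_threshold is None:
            return
        thr = self.fix_threshold * self.epsilon
        for k, arc in enumerate(self.net.arcs):
            if arc.kind != "transition":
                continue
            rc = self.reduced_cost(2 * k)
            if not self.active[k]:
                if rc <= thr:
                    self.active[k] = True
            elif self.resid[2 * k] == 1 and rc > thr:
                # carries no flow and is far from admissible: clip
                self.active[k] = False

    def run(self) -> None:
        """Main cost-scaling loop: ε ← ε/2, saturate, RESTORE, refine."""
        if self.m == 0:
            return
        eps = self.eps0
        while eps > 1:
            eps >>= 1
            self.epsilon = eps
            self._recheck_fixed_arcs()
            self.saturate_admissible()
            self.restore()
            self.stats.phases += 1
            self.stats.phase_log.append(
                {
                    "epsilon": eps,
                    "eps_optimal": self.check_eps_optimality(eps, all_arcs=False),
                    "total_excess": self.total_excess(),
                }
            )
            while eps > 1 and self.price_refinement():
                eps >>= 1
                self.epsilon = eps
        if self.fix_threshold is not None:
            # final optimality check over ALL arcs; resume with everything
            # active if a clipped arc turned out to be needed
            while self._violating_arcs(1):
                self.active[:] = True
                self.epsilon = 1
                self.saturate_admissible()
                self.restore()
        if self.total_excess() != 0 or (self.excess != 0).any():
            raise SolverError("termination with imbalanced nodes")


def check_eps_optimality(state: SolverState, eps: int, all_arcs: bool = True) -> bool:
    """Module-level verifier (internal ε units): see
    :meth:`SolverState.check_eps_optimality`."""
    return state.check_eps_optimality(eps, all_arcs=all_arcs)


def solve(
    net: CirculationNetwork,
    fix_threshold: Optional[float] = None,
) -> Tuple[np.ndarray, int, SolverState]:
    """Solve the minimum-cost circulation problem on ``net``.

    Returns ``(flow, total_cost, state)`` where ``flow`` is binary over the
    network's forward arcs and ``total_cost`` is in quantized integer cost
    units (divide by ``net.scale`` for the real-cost scale).  The zero
    circulation is the feasible start; with all costs nonnegative the zero
    circulation is already optimal and is returned unchanged.
    """
    state = SolverState(net, fix_threshold=fix_threshold)
    state.run()
    return state.flow(), state.total_cost_int(), state
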