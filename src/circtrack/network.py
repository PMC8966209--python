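"""Circulation-network construction from gated detections.

Every detection ``i`` becomes a pre-node ``o_i`` and a post-node ``h_i``
joined by an observation arc carrying the observation cost; a single dummy
node ``s`` sends an entrance arc to every pre-node and receives an exit arc
from every post-node; a transition arc ``h_i -> o_j`` exists for every gated
candidate pair.  All capacities are one.  Structural facts used by the
solver and its analysis:

* removing ``s`` leaves a DAG, because transition arcs point strictly
  forward in time — hence every directed cycle passes through ``s`` and a
  circulation decomposes into arc-disjoint s-cycles, one per trajectory;
* every node except ``s`` has a single in-arc or a single out-arc
  (an overwhelming unit-vertex-capacity graph with one exception).

Real costs are quantized to integers: ``cost_int = round(S * cost_real)``
(half away from zero), so the cost-scaling solver's integer termination
argument applies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .costs import (
    CostConfig,
    DistanceECDF,
    boundary_cost,
    detection_cost,
    gt_linkage_cost,
    transition_cost,
)
from .detections import DetectionSet

__all__ = [
    "Arc",
    "CirculationNetwork",
    "build_circulation_network",
    "build_flow_network",
    "assert_structure",
    "StructureError",
]

ARC_KINDS = ("enter", "observation", "exit", "transition")


class StructureError(AssertionError):
    """A constructed network violates a structural guarantee."""


@dataclass
class Arc:
    tail: int
    head: int
    cost_real: float
    cost_int: int
    kind: str
    det_pair: Tuple[Optional[int], Optional[int]]
    capacity: int = 1


def _quantize(cost: float, scale: int) -> int:
    """Round half away from zero after scaling."""
    x = cost * scale
    return int(np.floor(x + 0.5)) if x >= 0 else int(np.ceil(x - 0.5))


@dataclass
class CirculationNetwork:
    """Unit-capacity circulation network over 2D+1 nodes (s = node 0).

    Node layout: ``s = 0``; detection ``i`` has pre-node ``1 + 2i`` and
    post-node ``2 + 2i``.  Arcs are stored in a fixed deterministic order
    (enter, observation, exit per detection, then transitions sorted by
    (i, gap, j)) so solver runs are reproducible.
    """

    n_detections: int
    arcs: List[Arc]
    scale: int
    s: int = 0

    @property
    def n_nodes(self) -> int:
        return 2 * self.n_detections + 1

    @property
    def n_arcs(self) -> int:
        return len(self.arcs)

    def pre_node(self, i: int) -> int:
        return 1 + 2 * i

    def post_node(self, i: int) -> int:
        return 2 + 2 * i

    def detection_of(self, node: int) -> Tuple[int, str]:
        """Inverse of the node layout: (detection index, 'pre'|'post')."""
        if node == self.s:
            raise ValueError("s is not a detection node")
        i, r = divmod(node - 1, 2)
        return i, "pre" if r == 0 else "post"

    def int_costs(self) -> np.ndarray:
        return np.array([a.cost_int for a in self.arcs], dtype=np.int64)

    def real_costs(self) -> np.ndarray:
        return np.array([a.cost_real for a in self.arcs], dtype=float)

    def max_abs_cost(self) -> int:
        if not self.arcs:
            return 0
        return int(max(abs(a.cost_int) for a in self.arcs))

    def with_costs(self, real_costs: Sequence[float]) -> "CirculationNetwork":
        """Same topology with replaced (re-quantized) arc costs."""
        real_costs = np.asarray(real_costs, dtype=float)
        if real_costs.shape != (self.n_arcs,):
            raise ValueError("need one cost per arc")
        arcs = [
            Arc(a.tail, a.head, float(c), _quantize(float(c), self.scale),
                a.kind, a.det_pair)
            for a, c in zip(self.arcs, real_costs)
        ]
        return CirculationNetwork(self.n_detections, arcs, self.scale)

    def to_dimacs(self) -> str:
        """DIMACS min-cost-flow dump of the circulation network (1-based
        nodes, zero supplies) for cross-checks with external solvers."""
        lines = [f"p min {self.n_nodes} {self.n_arcs}"]
        for a in self.arcs:
            lines.append(f"a {a.tail + 1} {a.head + 1} 0 {a.capacity} {a.cost_int}")
        return "\n".join(lines) + "\n"


def build_circulation_network(
    dets: DetectionSet,
    config: CostConfig,
    candidates: Sequence[Tuple[int, int, float, int]],
    ecdf: Optional[DistanceECDF] = None,
) -> CirculationNetwork:
    """Assemble the circulation network from detections and gated candidates.

    ``candidates`` are ``(i, j, distance, gap)`` tuples from
    :func:`~circtrack.costs.gate_candidates`; they must point strictly
    forward in time.  ``ecdf`` converts distances to transition costs; when
    omitted, the raw distance is used as the cost (useful for toy networks).
    """
    D = len(dets)
    arcs: List[Arc] = []
    enter = boundary_cost(config.p_enter, config.p_min)
    exit_ = boundary_cost(config.p_exit, config.p_min)
    for det in dets:
        if config.use_gt_linkage:
            obs = gt_linkage_cost(enter, exit_)
        else:
            obs = detection_cost(config.beta_for(det))
        i = det.index
        o, h = 1 + 2 * i, 2 + 2 * i
        arcs.append(Arc(0, o, enter, _quantize(enter, config.cost_scale),
                        "enter", (i, None)))
        arcs.append(Arc(o, h, obs, _quantize(obs, config.cost_scale),
                        "observation", (i, None)))
        arcs.append(Arc(h, 0, exit_, _quantize(exit_, config.cost_scale),
                        "exit", (i, None)))
    ordered = sorted(candidates, key=lambda t: (t[0], t[3], t[1]))
    for i, j, dist, gap in ordered:
        if dets[j].frame <= dets[i].frame:
            raise StructureError(
                f"candidate {i}->{j} is not forward in time "
                f"(frames {dets[i].frame} -> {dets[j].frame})"
            )
        if gap != dets[j].frame - dets[i].frame:
            raise StructureError(f"candidate {i}->{j}: gap {gap} inconsistent")
        if ecdf is None:
            c = float(dist)
        else:
            c = transition_cost(
                ecdf, dist, is_jump=gap > 1,
                p_jump=config.p_jump if gap > 1 else None,
                p_min=config.p_min,
            )
        arcs.append(Arc(2 + 2 * i, 1 + 2 * j, c, _quantize(c, config.cost_scale),
                        "transition", (i, j)))
    return CirculationNetwork(D, arcs, config.cost_scale)


@dataclass
class FlowNetwork:
    """The flow-network twin: s split into a source (node 0, excess K) and a
    sink t (last node, deficit K); all other arcs preserved."""

    n_nodes: int
    source: int
    sink: int
    arcs: List[Arc]
    K: int


def build_flow_network(net: CirculationNetwork, K: int) -> FlowNetwork:
    """Split the dummy node into source/sink so each s-cycle becomes an s-t
    path; used by the reference solvers to realize the flow-vs-circulation
    equivalence (min over K of the flow optimum = circulation optimum)."""
    if K < 0:
        raise ValueError("K must be >= 0")
    t = net.n_nodes  # new sink
    arcs = []
    for a in net.arcs:
        head = t if a.head == net.s and a.kind == "exit" else a.head
        arcs.append(Arc(a.tail, head, a.cost_real, a.cost_int, a.kind, a.det_pair))
    return FlowNetwork(net.n_nodes + 1, net.s, t, arcs, K)


def assert_structure(net: CirculationNetwork) -> dict:
    """Verify the structural guarantees, returning a diagnostic report.

    Checks: node/arc counts; G minus s is a DAG (by Kahn's topological
    sort); every non-s node has a single in-arc or a single out-arc
    (unit vertex capacity).  Raises :class:`StructureError` on violation.
    """
    n = net.n_nodes
    indeg = np.zeros(n, dtype=int)
    outdeg = np.zeros(n, dtype=int)
    adj: List[List[int]] = [[] for _ in range(n)]
    for a in net.arcs:
        if a.capacity != 1:
            raise StructureError(f"arc {a.tail}->{a.head} has capacity {a.capacity}")
        outdeg[a.tail] += 1
        indeg[a.head] += 1
        if a.tail != net.s and a.head != net.s:
            adj[a.tail].append(a.head)
    # unit vertex capacity for every node but s
    for v in range(n):
        if v == net.s:
            continue
        if indeg[v] > 1 and outdeg[v] > 1:
            raise StructureError(
                f"node {v} has {indeg[v]} in-arcs and {outdeg[v]} out-arcs; "
                "unit-vertex-capacity violated"
            )
    # Kahn topological sort on G \ s
    indeg_sub = np.zeros(n, dtype=int)
    for v in range(n):
        for w in adj[v]:
            indeg_sub[w] += 1
    stack = [v for v in range(n) if v != net.s and indeg_sub[v] == 0]
    seen = 0
    while stack:
        v = stack.pop()
        seen += 1
        for w in adj[v]:
            indeg_sub[w] -= 1
            if indeg_sub[w] == 0:
                stack.append(w)
    if seen != n - 1:
        raise StructureError("G minus s contains a directed cycle")
    n_trans = sum(1 for a in net.arcs if a.kind == "transition")
    report = {
        "n_nodes": n,
        "n_arcs": net.n_arcs,
        "n_detections": net.n_detections,
        "n_transitions": n_trans,
        "dag_ok": True,
        "unit_vertex_capacity_ok": True,
        "counts_ok": (n == 2 * net.n_detections + 1
                      and net.n_arcs == 3 * net.n_detections + n_trans),
    }
    if not report["counts_ok"]:
        raise StructureError("node/arc counts violate n=2D+1, m=3D+T")
    return report
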