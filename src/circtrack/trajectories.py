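"""Trajectory decoding from an optimal circulation, and CLEAR-MOT metrics.

A feasible binary circulation on the tracking network decomposes into
arc-disjoint cycles through the dummy node ``s``; each cycle
``s → o_{k1} → h_{k1} → … → h_{kn} → s`` is one trajectory, so the number
of trajectories equals the flow through ``s``.

Evaluation follows the standard CLEAR-MOT protocol on point detections:
per-frame matching of predictions to ground-truth objects within a match
radius — persisting last-frame correspondences are kept first, the rest
matched greedily by distance — then MOTA, MOTP (mean matched distance),
IDF1, identity switches (IDS), mostly-tracked/mostly-lost fractions and the
false-alarm rate are accumulated.  IDF1 uses an optimal global assignment
between ground-truth and predicted identities (Hungarian algorithm).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import linear_sum_assignment

from .detections import DetectionSet
from .network import CirculationNetwork

__all__ = ["Trajectory", "Solution", "flow_to_trajectories", "evaluate"]


@dataclass
class Trajectory:
    """A temporally ordered chain of detection indices with its cycle cost."""

    detections: List[int]
    cost: float = 0.0

    def __post_init__(self) -> None:
        if not self.detections:
            raise ValueError("a trajectory cannot be empty")

    def __len__(self) -> int:
        return len(self.detections)


@dataclass
class Solution:
    """A set of pairwise disjoint trajectories decoded from a circulation."""

    trajectories: List[Trajectory] = field(default_factory=list)
    total_cost: float = 0.0
    total_cost_int: int = 0

    @property
    def flow_amount(self) -> int:
        """K — the number of trajectories = the flow through s."""
        return len(self.trajectories)

    def assignment(self, n_detections: int) -> np.ndarray:
        """Track id per detection (-1 for unassigned), ids in report order."""
        out = np.full(n_detections, -1, dtype=int)
        for tid, traj in enumerate(self.trajectories):
            for di in traj.detections:
                if out[di] != -1:
                    raise ValueError(f"detection {di} appears in two trajectories")
                out[di] = tid
        return out

    def links(self) -> List[Tuple[int, int]]:
        """All (i, j) detection links across all trajectories."""
        out = []
        for traj in self.trajectories:
            out.extend(zip(traj.detections[:-1], traj.detections[1:]))
        return out


def flow_to_trajectories(
    net: CirculationNetwork, flow: Sequence[int], dets: Optional[DetectionSet] = None
) -> Solution:
    """Decode the saturated cycles of a feasible binary circulation.

    Walks each saturated enter arc out of ``s`` along saturated arcs back to
    ``s``; every saturated arc is consumed exactly once.  Trajectories are
    reported sorted by (first frame, first detection index); each carries
    the real-cost sum of its cycle.
    """
    flow = np.asarray(flow, dtype=int)
    if flow.shape != (net.n_arcs,):
        raise ValueError("flow must have one value per arc")
    if not np.isin(flow, (0, 1)).all():
        raise ValueError("flow must be binary on forward arcs")
    # conservation check and successor maps
    balance = np.zeros(net.n_nodes, dtype=int)
    succ: Dict[int, List[Tuple[int, int]]] = {}
    for k, a in enumerate(net.arcs):
        if flow[k]:
            balance[a.tail] += 1
            balance[a.head] -= 1
            succ.setdefault(a.tail, []).append((a.head, k))
    if (balance != 0).any():
        bad = int(np.flatnonzero(balance)[0])
        raise ValueError(f"flow does not conserve at node {bad}")
    for v, lst in succ.items():
        if v != net.s and len(lst) > 1:
            raise ValueError(f"node {v} has {len(lst)} saturated out-arcs")
    trajectories = []
    starts = sorted(succ.get(net.s, []), key=lambda t: t[0])
    for start_node, start_arc in starts:
        chain: List[int] = []
        cost = net.arcs[start_arc].cost_real
        node = start_node
        while node != net.s:
            i, role = net.detection_of(node)
            if role == "pre":
                chain.append(i)
            (nxt, k), = succ[node]
            cost += net.arcs[k].cost_real
            node = nxt
        trajectories.append(Trajectory(chain, cost))
    if dets is not None:
        trajectories.sort(key=lambda t: (dets[t.detections[0]].frame, t.detections[0]))
    else:
        trajectories.sort(key=lambda t: t.detections[0])
    total_real = sum(t.cost for t in trajectories)
    total_int = int(np.dot([a.cost_int for a in net.arcs], flow))
    return Solution(trajectories, total_real, total_int)


@dataclass
class MetricReport:
    """CLEAR-MOT summary.  Percentages are on the 0–100 scale."""

    mota: float
    motp: float
    idf1: float
    ids: int
    mt: float
    ml: float
    far: float
    n_matches: int
    n_misses: int
    n_false_positives: int
    n_gt: int

    def as_dict(self) -> dict:
        return {
            "MOTA": self.mota, "MOTP": self.motp, "IDF1": self.idf1,
            "IDS": self.ids, "MT": self.mt, "ML": self.ml, "FAR": self.far,
            "matches": self.n_matches, "misses": self.n_misses,
            "false_positives": self.n_false_positives, "gt": self.n_gt,
        }

    def __str__(self) -> str:
        return (
            f"MOTA {self.mota:6.1f}%  MOTP {self.motp:7.3f}  IDF1 {self.idf1:6.1f}%  "
            f"IDS {self.ids:4d}  MT {self.mt:5.1f}%  ML {self.ml:5.1f}%  "
            f"FAR {self.far:6.2f}"
        )


def _frame_tables(frames, ids, positions, n_frames):
    per_frame: List[Dict[int, np.ndarray]] = [dict() for _ in range(n_frames)]
    for f, i, pos in zip(frames, ids, positions):
        per_frame[int(f)][int(i)] = np.asarray(pos, dtype=float)
    return per_frame


def evaluate(
    solution: Solution,
    ground_truth_ids: Sequence[int],
    ground_truth_frames: Sequence[int],
    ground_truth_positions: np.ndarray,
    dets: DetectionSet,
    match_radius: float,
) -> MetricReport:
    """CLEAR-MOT evaluation of ``solution`` against ground-truth footprints.

    Ground truth is given as parallel arrays (identity, frame, position) per
    true object footprint.  Matching is per frame within ``match_radius``,
    preferring persisting correspondences; IDS counts correspondence changes
    of a ground-truth object between its consecutively matched frames.
    """
    gt_frames = np.asarray(ground_truth_frames, dtype=int)
    gt_ids = np.asarray(ground_truth_ids, dtype=int)
    gt_pos = np.atleast_2d(np.asarray(ground_truth_positions, dtype=float))
    n_frames = dets.n_frames
    if gt_frames.size and (gt_frames.min() < 0 or gt_frames.max() >= n_frames):
        raise ValueError("ground-truth frames outside the detection frame range")
    gt_table = _frame_tables(gt_frames, gt_ids, gt_pos, n_frames)

    assign = solution.assignment(len(dets))
    pr_frames, pr_ids, pr_pos = [], [], []
    for det in dets:
        if assign[det.index] >= 0:
            pr_frames.append(det.frame)
            pr_ids.append(int(assign[det.index]))
            pr_pos.append(det.position)
    pr_table = _frame_tables(pr_frames, pr_ids,
                             pr_pos if pr_pos else np.empty((0, dets.dim)), n_frames)

    matches = misses = false_pos = ids_switches = 0
    dist_sum = 0.0
    last_match: Dict[int, int] = {}  # gt id -> pred id at last matched frame
    gt_track_frames: Dict[int, int] = {}
    gt_track_matched: Dict[int, int] = {}
    id_match_counts: Dict[Tuple[int, int], int] = {}
    n_pred_per_id: Dict[int, int] = {}
    n_gt_per_id: Dict[int, int] = {}

    for f in range(n_frames):
        gts = gt_table[f]
        prs = pr_table[f]
        for g in gts:
            gt_track_frames[g] = gt_track_frames.get(g, 0) + 1
            n_gt_per_id[g] = n_gt_per_id.get(g, 0) + 1
        for pid in prs:
            n_pred_per_id[pid] = n_pred_per_id.get(pid, 0) + 1
        taken_pr = set()
        frame_pairs: List[Tuple[int, int, float]] = []
        # keep persisting correspondences first
        for g, gpos in gts.items():
            pid = last_match.get(g)
            if pid is not None and pid in prs and pid not in taken_pr:
                d = float(np.linalg.norm(prs[pid] - gpos))
                if d <= match_radius:
                    frame_pairs.append((g, pid, d))
                    taken_pr.add(pid)
        matched_gt = {g for g, _, _ in frame_pairs}
        # greedy nearest for the rest
        rest_g = [g for g in gts if g not in matched_gt]
        rest_p = [p for p in prs if p not in taken_pr]
        cand = []
        for g in rest_g:
            for p in rest_p:
                d = float(np.linalg.norm(prs[p] - gts[g]))
                if d <= match_radius:
                    cand.append((d, g, p))
        cand.sort()
        for d, g, p in cand:
            if g in matched_gt or p in taken_pr:
                continue
            frame_pairs.append((g, p, d))
            matched_gt.add(g)
            taken_pr.add(p)
        for g, p, d in frame_pairs:
            matches += 1
            dist_sum += d
            gt_track_matched[g] = gt_track_matched.get(g, 0) + 1
            id_match_counts[(g, p)] = id_match_counts.get((g, p), 0) + 1
            if g in last_match and last_match[g] != p:
                ids_switches += 1
            last_match[g] = p
        misses += len(gts) - len(matched_gt)
        false_pos += len(prs) - len(taken_pr)

    n_gt = int(sum(n_gt_per_id.values()))
    mota = 100.0 * (1.0 - (misses + false_pos + ids_switches) / n_gt) if n_gt else 0.0
    motp = dist_sum / matches if matches else 0.0
    # IDF1: optimal global 1-1 assignment of gt ids to pred ids
    g_list = sorted(n_gt_per_id)
    p_list = sorted(n_pred_per_id)
    idtp = 0
    if g_list and p_list:
        overlap = np.zeros((len(g_list), len(p_list)), dtype=float)
        for (g, p), c in id_match_counts.items():
            overlap[g_list.index(g), p_list.index(p)] = c
        row, col = linear_sum_assignment(-overlap)
        idtp = int(overlap[row, col].sum())
    denom = n_gt + sum(n_pred_per_id.values())
    idf1 = 100.0 * 2.0 * idtp / denom if denom else 0.0
    ratios = [gt_track_matched.get(g, 0) / gt_track_frames[g] for g in gt_track_frames]
    n_tracks = len(ratios)
    mt = 100.0 * sum(r >= 0.8 for r in ratios) / n_tracks if n_tracks else 0.0
    ml = 100.0 * sum(r <= 0.2 for r in ratios) / n_tracks if n_tracks else 0.0
    far = false_pos / n_frames if n_frames else 0.0
    return MetricReport(mota, motp, idf1, ids_switches, mt, ml, far,
                        matches, misses, false_pos, n_gt)
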