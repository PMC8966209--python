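"""Arc-cost model for the MAP data-association objective.

The MAP formulation assigns four kinds of costs:

* observation cost ``C_i = log(beta_i / (1 - beta_i))`` — negative for
  detections more likely real than spurious (beta < 1/2);
* entrance/exit costs ``C_en = -log P_enter``, ``C_ex = -log P_exit``;
* transition cost ``C_ij = -log p`` where ``p`` is the p-value of the
  displacement between the two detections under an empirical distribution of
  true inter-frame displacements; jump (gap > 1) links additionally pay
  ``-log p_jump``.

``P_enter``/``P_exit`` can be estimated from per-frame detection counts:
a net increase of the count between adjacent frames is read as that many
trajectories starting, a net decrease as that many ending; the first frame's
population counts as births and the last frame's as deaths so every
trajectory has exactly one of each.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, asdict
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .detections import DetectionSet

__all__ = [
    "CostConfig",
    "DistanceECDF",
    "detection_cost",
    "boundary_cost",
    "fit_distance_ecdf",
    "transition_cost",
    "estimate_rates_from_counts",
    "gt_linkage_cost",
    "gate_candidates",
]

logger = logging.getLogger(__name__)


@dataclass
class CostConfig:
    """Parameters controlling every arc cost.

    Attributes
    ----------
    p_enter, p_exit : float
        Probability of a trajectory starting / ending at a detection.
    default_beta : float
        False-positive probability assigned to detections without one.
    beta_from_confidence : bool
        If true, detections carrying a confidence get beta = 1 - confidence
        (a convention: detectors rarely publish a calibrated beta).
    p_min : float
        Floor applied to every probability before a logarithm, so no cost is
        infinite.
    knn : int
        Candidate links per detection per future frame.
    jump_window : int
        Maximum frame gap J of a transition arc (J > 1 enables jump arcs).
    p_jump : float or None
        Probability of a jump inside a trajectory; when set, gap > 1 arcs
        cost -log(p * p_jump).
    cost_scale : int
        Quantization scale S: integer arc cost = round(S * real cost).
    use_gt_linkage : bool
        Replace C_i by -(C_en + C_ex) so no detection is ever dropped
        (appropriate when detections are ground truth).
    """

    p_enter: float = 0.1
    p_exit: float = 0.1
    default_beta: float = 0.4
    beta_from_confidence: bool = False
    p_min: float = 1e-9
    knn: int = 3
    jump_window: int = 2
    p_jump: Optional[float] = None
    cost_scale: int = 10**6
    use_gt_linkage: bool = False

    def __post_init__(self) -> None:
        for name in ("p_enter", "p_exit"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{name} must lie in (0, 1], got {v}")
        if not (0.0 < self.default_beta < 1.0):
            raise ValueError("default_beta must lie in (0, 1)")
        if self.p_min <= 0:
            raise ValueError("p_min must be positive")
        if self.knn < 1 or self.jump_window < 1:
            raise ValueError("knn and jump_window must be >= 1")
        if self.cost_scale < 1:
            raise ValueError("cost_scale must be >= 1")
        if self.p_jump is not None and not (0.0 < self.p_jump <= 1.0):
            raise ValueError("p_jump must lie in (0, 1]")

    def clamp(self, p: float) -> float:
        """Clamp a probability into [p_min, 1]."""
        if p < self.p_min:
            return self.p_min
        return min(p, 1.0)

    def beta_for(self, detection) -> float:
        if detection.beta is not None:
            return detection.beta
        if self.beta_from_confidence and detection.confidence is not None:
            b = 1.0 - detection.confidence
            return min(max(b, self.p_min), 1.0 - self.p_min)
        return self.default_beta

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "CostConfig":
        return cls(**d)


@dataclass
class DistanceECDF:
    """Empirical distribution of true inter-frame displacement distances."""

    sorted_samples: np.ndarray
    n: int = field(init=False)

    def __post_init__(self) -> None:
        self.sorted_samples = np.sort(np.asarray(self.sorted_samples, dtype=float))
        self.n = self.sorted_samples.size
        if self.n < 1:
            raise ValueError("DistanceECDF needs at least one sample")
        if self.sorted_samples[0] < 0:
            raise ValueError("distances must be nonnegative")

    def survival(self, d) -> np.ndarray:
        """P(training distance >= d): fraction of samples at or above d.

        The smallest training distance maps to p = 1, so short displacements
        are free; distances beyond the support fall to 0 (clamped later).
        """
        d = np.asarray(d, dtype=float)
        below = np.searchsorted(self.sorted_samples, d, side="left")
        return (self.n - below) / self.n


def detection_cost(beta: float) -> float:
    """Observation cost ``log(beta / (1 - beta))``; negative iff beta < 1/2."""
    if not (0.0 < beta < 1.0):
        raise ValueError(f"beta must lie in (0, 1), got {beta}")
    return float(np.log(beta / (1.0 - beta)))


def boundary_cost(p: float, p_min: float = 1e-9) -> float:
    """Entrance/exit cost ``-log p`` (>= 0); p clamped to [p_min, 1]."""
    if p <= 0:
        warnings.warn(f"probability {p} clamped to p_min={p_min}", stacklevel=2)
        p = p_min
    p = min(max(p, p_min), 1.0)
    return float(-np.log(p))


def fit_distance_ecdf(distances: Sequence[float]) -> DistanceECDF:
    """Fit the empirical displacement distribution from training distances."""
    distances = np.asarray(distances, dtype=float)
    if distances.size == 0:
        raise ValueError("cannot fit an ECDF from no samples")
    return DistanceECDF(distances)


def transition_cost(
    ecdf: DistanceECDF,
    d: float,
    is_jump: bool = False,
    p_jump: Optional[float] = None,
    p_min: float = 1e-9,
) -> float:
    """Transition arc cost ``-log p`` (direct) or ``-log(p * p_jump)`` (jump).

    ``p`` is the survival p-value of the displacement ``d`` under the fitted
    distribution; clamping keeps the cost finite for out-of-support distances.
    """
    p = float(ecdf.survival(d))
    p = min(max(p, p_min), 1.0)
    cost = -np.log(p)
    if is_jump:
        if p_jump is None:
            raise ValueError("jump arcs need p_jump")
        cost += -np.log(min(max(p_jump, p_min), 1.0))
    return float(cost)


def estimate_rates_from_counts(
    frame_counts: Sequence[int], p_min: float = 1e-9
) -> Tuple[float, float]:
    """Estimate (p_enter, p_exit) from per-frame detection counts.

    Births = first frame's count plus every positive count increase; deaths =
    last frame's count plus every positive decrease.  Both are divided by the
    total number of detections.  Simultaneous births and deaths within one
    frame pair cancel in the counts, so both rates are biased low in that
    regime.
    """
    counts = np.asarray(frame_counts, dtype=int)
    if counts.size < 2:
        raise ValueError("need counts for at least two frames")
    diffs = np.diff(counts)
    births = counts[0] + int(diffs[diffs > 0].sum())
    deaths = counts[-1] + int(-diffs[diffs < 0].sum())
    total = int(counts.sum())
    if total == 0:
        return p_min, p_min
    p_enter = min(max(births / total, p_min), 1.0)
    p_exit = min(max(deaths / total, p_min), 1.0)
    return p_enter, p_exit


def gt_linkage_cost(enter_cost: float, exit_cost: float) -> float:
    """Observation cost ``-(C_en + C_ex)`` that makes every singleton cycle
    cost exactly zero, so no detection can be dropped by the optimum."""
    return -(enter_cost + exit_cost)


def gate_candidates(
    dets: DetectionSet,
    knn: int = 3,
    jump_window: int = 1,
    predicted_positions: Optional[np.ndarray] = None,
) -> List[Tuple[int, int, float, int]]:
    """k-nearest-neighbor gating of transition candidates.

    For each detection ``i`` and each gap ``g`` in ``1..jump_window``, emit
    its ``knn`` nearest detections in frame(i)+g as ``(i, j, distance, gap)``
    tuples, measured from ``predicted_positions[i]`` when given (velocity
    gating) else from the detection's own position.  Ties in distance break
    toward the smaller detection index; output is sorted by (i, gap, j).
    """
    if knn < 1:
        raise ValueError("knn must be >= 1")
    if jump_window < 1:
        raise ValueError("jump_window must be >= 1")
    groups = dets.by_frame()
    positions = dets.positions()
    if predicted_positions is None:
        sources = positions
    else:
        sources = np.asarray(predicted_positions, dtype=float)
        if sources.shape != positions.shape:
            raise ValueError("predicted_positions must match detections shape")
    out: List[Tuple[int, int, float, int]] = []
    for det in dets:
        for gap in range(1, jump_window + 1):
            f = det.frame + gap
            if f >= dets.n_frames:
                break
            targets = groups[f]
            if not targets:
                continue
            tpos = positions[targets]
            dists = np.linalg.norm(tpos - sources[det.index], axis=1)
            # stable sort on (distance, index): index tie-break
            order = np.lexsort((np.asarray(targets), dists))[:knn]
            for o in order:
                out.append((det.index, targets[o], float(dists[o]), gap))
    out.sort(key=lambda t: (t[0], t[3], t[1]))
    return out
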