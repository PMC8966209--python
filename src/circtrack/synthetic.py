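"""Synthetic multi-frame detection data with known ground-truth identities.

The generator emulates the regimes where distance-based linking is the
method of choice (particle and cell recordings): point objects moving
slowly relative to their spacing, with object births and deaths, missed
detections, localization noise, and uniform false positives.  Each
simulated object carries an identity, so every tracking stage can be
scored without external data.  Sub-streams of the seeded generator are
derived per concern (motion, noise, misses, false positives), so toggling
false-positive injection does not perturb trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

from .detections import DetectionSet

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate",
    "nn_distance_samples",
    "true_link_solution",
]


@dataclass
class SimulationConfig:
    """Simulation parameters.

    Defaults emulate a well-separated slow-motion recording: 20 objects in
    a 100x100 arena over 50 frames, per-frame displacement about 1 unit
    (speed_scale), small localization noise, and error rates off — the
    clean regime; noise regimes are opted into per study.
    """

    n_objects_init: int = 20
    n_frames: int = 50
    dim: int = 2
    arena: Tuple[float, ...] = (100.0, 100.0)
    motion: str = "brownian"  # or "constant_velocity"
    speed_scale: float = 1.0
    birth_rate: float = 0.0  # expected births per frame
    death_rate: float = 0.0  # per object per frame
    miss_rate: float = 0.0
    fp_rate: float = 0.0  # expected false positives per frame
    noise_sigma: float = 0.1
    velocity_groups: Optional[int] = None  # coherent streams (constant_velocity)
    min_separation: float = 0.0  # rejection-sampled spacing of object starts
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dim not in (2, 3):
            raise ValueError("dim must be 2 or 3")
        if len(self.arena) != self.dim:
            raise ValueError("arena extents must match dim")
        if not (0.0 <= self.miss_rate < 1.0):
            raise ValueError("miss_rate must lie in [0, 1)")
        for name in ("birth_rate", "death_rate", "fp_rate", "noise_sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.motion not in ("brownian", "constant_velocity"):
            raise ValueError(f"unknown motion model {self.motion!r}")
        if self.velocity_groups is not None and self.velocity_groups < 1:
            raise ValueError("velocity_groups must be >= 1")


@dataclass
class GroundTruth:
    """True object footprints: identity/frame/position per footprint, and
    the identity (or -1 for false positives) of every emitted detection."""

    ids: np.ndarray
    frames: np.ndarray
    positions: np.ndarray
    detection_ids: np.ndarray  # per detection; -1 = false positive

    def true_trajectories(self) -> List[List[int]]:
        """Footprint row indices grouped per object, in frame order."""
        out = {}
        for row, (i, f) in enumerate(zip(self.ids, self.frames)):
            out.setdefault(int(i), []).append((int(f), row))
        return [[r for _, r in sorted(v)] for _, v in sorted(out.items())]


def simulate(config: SimulationConfig) -> Tuple[DetectionSet, GroundTruth]:
    """Run the simulation; fully reproducible from ``config.seed``.

    Objects move per the configured motion model with reflective arena
    boundaries; each live object is detected per frame with probability
    ``1 - miss_rate`` plus isotropic Gaussian localization noise; false
    positives are Poisson per frame, uniform over the arena, with no
    identity.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_motion, rng_life, rng_noise, rng_miss, rng_fp = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )
    extents = np.asarray(config.arena, dtype=float)
    dim = config.dim

    group_dirs = None
    if config.motion == "constant_velocity" and config.velocity_groups:
        # coherent streams: shared headings emulate tissue-like flows
        g = rng_motion.normal(size=(config.velocity_groups, dim))
        group_dirs = g / np.linalg.norm(g, axis=1, keepdims=True)

    def draw_velocity(k: int) -> np.ndarray:
        if config.motion != "constant_velocity":
            return np.zeros(dim)
        if group_dirs is not None:
            return group_dirs[k % len(group_dirs)] * config.speed_scale
        d_ = rng_motion.normal(size=dim)
        return d_ / np.linalg.norm(d_) * config.speed_scale

    def place(existing: List[np.ndarray]) -> np.ndarray:
        """Uniform position, rejection-sampled against min_separation."""
        for _ in range(10_000):
            p = rng_motion.uniform(0, extents)
            if config.min_separation <= 0 or not existing or (
                min(np.linalg.norm(p - q) for q in existing) >= config.min_separation
            ):
                return p
        raise RuntimeError("could not place objects at the requested separation")

    placed: List[np.ndarray] = []
    for _ in range(config.n_objects_init):
        placed.append(place(placed))
    positions = np.stack(placed) if placed else np.empty((0, dim))
    velocities = np.stack([draw_velocity(i) for i in range(config.n_objects_init)]) \
        if config.n_objects_init else np.empty((0, dim))
    alive = list(range(config.n_objects_init))
    next_id = config.n_objects_init
    obj_pos = {i: positions[i].copy() for i in alive}
    obj_vel = {i: velocities[i].copy() for i in alive}

    gt_ids: List[int] = []
    gt_frames: List[int] = []
    gt_pos: List[np.ndarray] = []
    det_frames: List[int] = []
    det_pos: List[np.ndarray] = []
    det_ids: List[int] = []

    for frame in range(config.n_frames):
        if frame > 0:
            # deaths
            alive = [i for i in alive if rng_life.random() >= config.death_rate]
            # motion
            for i in alive:
                if config.motion == "brownian":
                    step = rng_motion.normal(scale=config.speed_scale, size=dim)
                else:
                    step = obj_vel[i]
                p = obj_pos[i] + step
                # reflect off the walls, flipping velocity components
                for d in range(dim):
                    if p[d] < 0:
                        p[d] = -p[d]
                        obj_vel[i][d] *= -1
                    elif p[d] > extents[d]:
                        p[d] = 2 * extents[d] - p[d]
                        obj_vel[i][d] *= -1
                obj_pos[i] = p
            # births
            for _ in range(rng_life.poisson(config.birth_rate)):
                obj_pos[next_id] = place([obj_pos[i] for i in alive])
                obj_vel[next_id] = draw_velocity(next_id)
                alive.append(next_id)
                next_id += 1
        for i in alive:
            gt_ids.append(i)
            gt_frames.append(frame)
            gt_pos.append(obj_pos[i].copy())
            if rng_miss.random() >= config.miss_rate:
                noisy = obj_pos[i] + rng_noise.normal(scale=config.noise_sigma, size=dim)
                det_frames.append(frame)
                det_pos.append(noisy)
                det_ids.append(i)
        for _ in range(rng_fp.poisson(config.fp_rate)):
            det_frames.append(frame)
            det_pos.append(rng_fp.uniform(0, extents, size=dim))
            det_ids.append(-1)

    if det_frames:
        order = np.lexsort((np.arange(len(det_frames)), np.asarray(det_frames)))
        det_id_arr = np.asarray(det_ids)[order]
        dets = DetectionSet.from_arrays(
            np.asarray(det_frames)[order],
            np.stack(det_pos)[order],
            frame_labels=range(config.n_frames),
        )
    else:
        det_id_arr = np.zeros(0, dtype=int)
        dets = DetectionSet([], list(range(config.n_frames)))
    gt = GroundTruth(
        np.asarray(gt_ids, dtype=int),
        np.asarray(gt_frames, dtype=int),
        np.stack(gt_pos) if gt_pos else np.empty((0, dim)),
        det_id_arr,
    )
    return dets, gt


def nn_distance_samples(dets: DetectionSet) -> np.ndarray:
    """Nearest-neighbor distances to the next frame, one per detection with
    a nonempty successor frame — the training sample for the empirical
    displacement distribution (valid when motion is slow relative to
    object spacing, so true successors dominate the nearest neighbors)."""
    groups = dets.by_frame()
    positions = dets.positions()
    samples = []
    for det in dets:
        f = det.frame + 1
        if f >= dets.n_frames or not groups[f]:
            continue
        tpos = positions[groups[f]]
        samples.append(float(np.min(np.linalg.norm(tpos - det.position, axis=1))))
    return np.asarray(samples)


def true_link_solution(dets: DetectionSet, gt: GroundTruth, jump_window: int = 1):
    """The ground-truth association as a Solution over the emitted
    detections: each object's detections chained in frame order, split
    wherever the frame gap exceeds ``jump_window`` (an unlinkable stretch of
    missed detections); false positives stay unassigned.  This is the
    reference a tracker's output can be compared against, and the input for
    estimator-recovery studies on data with known gap structure."""
    from .trajectories import Solution, Trajectory

    by_obj = {}
    for det, oid in zip(dets, gt.detection_ids):
        if oid >= 0:
            by_obj.setdefault(int(oid), []).append((det.frame, det.index))
    chains: List[List[int]] = []
    for _, lst in sorted(by_obj.items()):
        lst.sort()
        chain = [lst[0][1]]
        for (f1, _), (f2, i2) in zip(lst[:-1], lst[1:]):
            if f2 - f1 <= jump_window:
                chain.append(i2)
            else:
                chains.append(chain)
                chain = [i2]
        chains.append(chain)
    chains.sort(key=lambda c: (dets[c[0]].frame, c[0]))
    return Solution([Trajectory(c) for c in chains])
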