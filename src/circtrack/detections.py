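"""Detection data model and tabular I/O.

A *detection* is a single snapshot of an object in one frame: a time index, a
point position (2-D or 3-D), an optional detector confidence and a
false-positive probability ``beta``.  A :class:`DetectionSet` holds all
detections of a recording with frames remapped to a contiguous 0-based range
(jump-window semantics need contiguous time); the original frame labels are
kept so output files use the caller's numbering.

Two file dialects are supported:

* ``csv`` — header ``frame,x,y[,z][,conf]``, comma separated.
* ``motchallenge`` — the 10-column MOTChallenge text format
  ``frame,id,bb_left,bb_top,bb_width,bb_height,conf,x,y,z``; boxes are
  reduced to their centers on read.
"""

from __future__ import annotations

import csv as _csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, List, Optional, Sequence

import numpy as np

__all__ = [
    "Detection",
    "DetectionSet",
    "read_detections",
    "write_trajectories",
]


@dataclass
class Detection:
    """One detected object snapshot.

    Parameters
    ----------
    index : int
        Id unique within the dataset, contiguous from 0.
    frame : int
        Internal 0-based frame index.
    position : ndarray
        2 or 3 spatial coordinates (pixels or µm).
    confidence : float or None
        Detector confidence in [0, 1] when available.
    beta : float or None
        Probability that this detection is a false positive, in (0, 1).
        Filled in by the cost model when absent.
    """

    index: int
    frame: int
    position: np.ndarray
    confidence: Optional[float] = None
    beta: Optional[float] = None

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.frame < 0:
            raise ValueError(f"detection {self.index}: frame must be >= 0")
        if self.beta is not None and not (0.0 < self.beta < 1.0):
            raise ValueError(f"detection {self.index}: beta must lie in (0, 1)")


@dataclass
class DetectionSet:
    """All detections of one recording, sortable by (frame, index)."""

    detections: List[Detection] = field(default_factory=list)
    frame_labels: List[int] = field(default_factory=list)  # internal -> original

    def __post_init__(self) -> None:
        for expected, det in enumerate(self.detections):
            if det.index != expected:
                raise ValueError("detection indices must be 0..D-1 with no gaps")
        dims = {det.position.shape[0] for det in self.detections}
        if len(dims) > 1:
            raise ValueError(f"mixed position dimensionality: {sorted(dims)}")
        if not self.frame_labels and self.detections:
            n = max(d.frame for d in self.detections) + 1
            self.frame_labels = list(range(n))

    def __len__(self) -> int:
        return len(self.detections)

    def __iter__(self):
        return iter(self.detections)

    def __getitem__(self, i: int) -> Detection:
        return self.detections[i]

    @property
    def n_frames(self) -> int:
        return len(self.frame_labels)

    @property
    def dim(self) -> int:
        return self.detections[0].position.shape[0] if self.detections else 2

    def positions(self) -> np.ndarray:
        """(D, dim) array of all positions (empty (0, dim) when no detections)."""
        if not self.detections:
            return np.empty((0, self.dim))
        return np.stack([d.position for d in self.detections])

    def frames(self) -> np.ndarray:
        return np.array([d.frame for d in self.detections], dtype=int)

    def by_frame(self) -> List[List[int]]:
        """Detection indices grouped per internal frame."""
        groups: List[List[int]] = [[] for _ in range(self.n_frames)]
        for det in self.detections:
            groups[det.frame].append(det.index)
        return groups

    def frame_counts(self) -> np.ndarray:
        counts = np.zeros(self.n_frames, dtype=int)
        for det in self.detections:
            counts[det.frame] += 1
        return counts

    @classmethod
    def from_arrays(
        cls,
        frames: Sequence[int],
        positions: np.ndarray,
        confidences: Optional[Sequence[float]] = None,
        frame_labels: Optional[Sequence[int]] = None,
    ) -> "DetectionSet":
        """Build a DetectionSet, remapping frame labels to 0-based contiguous
        internal indices (order preserving)."""
        frames = np.asarray(frames, dtype=int)
        positions = np.atleast_2d(np.asarray(positions, dtype=float))
        if frames.size == 0:
            return cls([], [])
        if frame_labels is None:
            labels = sorted(set(int(f) for f in frames))
        else:
            labels = sorted(set(int(f) for f in frame_labels))
        remap = {lab: i for i, lab in enumerate(labels)}
        order = np.lexsort((np.arange(frames.size), frames))
        dets = []
        for new_idx, src in enumerate(order):
            conf = None if confidences is None else confidences[src]
            if conf is not None and conf < 0:  # MOTChallenge uses -1 for "absent"
                conf = None
            dets.append(
                Detection(
                    index=new_idx,
                    frame=remap[int(frames[src])],
                    position=positions[src],
                    confidence=conf,
                )
            )
        return cls(dets, labels)


def _parse_float(token: str, path: Path, lineno: int) -> float:
    try:
        return float(token)
    except ValueError:
        raise ValueError(f"{path}:{lineno}: malformed value {token!r}") from None


def read_detections(path, format: str = "csv") -> DetectionSet:
    """Read detections from ``path``.

    ``format='csv'`` expects a header ``frame,x,y[,z][,conf]``;
    ``format='motchallenge'`` expects the headerless 10-column det file, with
    boxes converted to center points (left + w/2, top + h/2).
    """
    path = Path(path)
    frames: List[int] = []
    positions: List[List[float]] = []
    confs: List[Optional[float]] = []
    if format == "csv":
        with open(path, newline="") as fh:
            reader = _csv.reader(fh)
            header = next(reader, None)
            if header is None:
                return DetectionSet([], [])
            header = [h.strip().lower() for h in header]
            if header[:2] != ["frame", "x"]:
                raise ValueError(f"{path}:1: expected header frame,x,y[,z][,conf]")
            has_z = "z" in header
            has_conf = "conf" in header
            ncol = 2 + (1 if has_z else 0) + (1 if has_conf else 0) + 1
            dim = 3 if has_z else 2
            for lineno, row in enumerate(reader, start=2):
                if not row or all(not c.strip() for c in row):
                    continue
                if len(row) != ncol:
                    raise ValueError(
                        f"{path}:{lineno}: expected {ncol} columns, got {len(row)}"
                    )
                vals = [_parse_float(c, path, lineno) for c in row]
                frames.append(int(vals[0]))
                positions.append(vals[1 : 1 + dim])
                confs.append(vals[1 + dim] if has_conf else None)
    elif format == "motchallenge":
        with open(path, newline="") as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line:
                    continue
                parts = line.split(",")
                if len(parts) < 7:
                    raise ValueError(f"{path}:{lineno}: expected >= 7 columns")
                vals = [_parse_float(p, path, lineno) for p in parts[:7]]
                frame, _id, left, top, w, h, conf = vals
                frames.append(int(frame))
                positions.append([left + w / 2.0, top + h / 2.0])
                confs.append(conf)
    else:
        raise ValueError(f"unknown format {format!r}")
    if not frames:
        return DetectionSet([], [])
    any_conf = any(c is not None for c in confs)
    return DetectionSet.from_arrays(
        frames, np.asarray(positions), confs if any_conf else None
    )


def write_trajectories(solution, dets: DetectionSet, path, format: str = "csv") -> None:
    """Write a tracking :class:`~circtrack.trajectories.Solution` to ``path``.

    One row per (track id, detection); original frame labels are restored.
    ``csv`` rows are ``frame,track_id,x,y[,z]``; ``motchallenge`` rows follow
    the result format with degenerate 1x1 boxes for point detections.
    """
    path = Path(path)
    dim = dets.dim
    rows = []
    for tid, traj in enumerate(solution.trajectories, start=1):
        for di in traj.detections:
            det = dets[di]
            rows.append((dets.frame_labels[det.frame], tid, det.position))
    rows.sort(key=lambda r: (r[0], r[1]))
    with open(path, "w", newline="") as fh:
        if format == "csv":
            writer = _csv.writer(fh)
            writer.writerow(["frame", "track_id", "x", "y"] + (["z"] if dim == 3 else []))
            for frame, tid, pos in rows:
                writer.writerow([frame, tid] + [repr(float(c)) for c in pos])
        elif format == "motchallenge":
            for frame, tid, pos in rows:
                left, top = pos[0] - 0.5, pos[1] - 0.5
                fh.write(
                    f"{frame},{tid},{left:.6f},{top:.6f},1,1,1,-1,-1,-1\n"
                )
        else:
            raise ValueError(f"unknown format {format!r}")


def read_trajectories(path, format: str = "csv"):
    """Read a result file back as a list of ``(frame_label, track_id, position)``
    rows, the inverse of :func:`write_trajectories` for round-trip checks."""
    path = Path(path)
    out = []
    with open(path, newline="") as fh:
        if format == "csv":
            reader = _csv.reader(fh)
            header = next(reader, None)
            if header is None:
                return out
            dim = 3 if "z" in [h.strip().lower() for h in header] else 2
            for row in reader:
                if not row:
                    continue
                out.append(
                    (int(float(row[0])), int(float(row[1])),
                     np.array([float(c) for c in row[2 : 2 + dim]]))
                )
        elif format == "motchallenge":
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                p = line.split(",")
                frame, tid = int(float(p[0])), int(float(p[1]))
                left, top, w, h = (float(x) for x in p[2:6])
                out.append((frame, tid, np.array([left + w / 2, top + h / 2])))
        else:
            raise ValueError(f"unknown format {format!r}")
    return out
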