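"""Shared fixtures: hand-built toy networks and detection sets."""

import numpy as np
import pytest
from hypothesis import settings as _hyp_settings

from circtrack.detections import Detection, DetectionSet

_hyp_settings.register_profile("repro", derandomize=True)
_hyp_settings.load_profile("repro")
from circtrack.network import Arc, CirculationNetwork


def make_detset(frames, positions):
    """DetectionSet from parallel frame/position lists (already ordered)."""
    dets = [
        Detection(index=i, frame=int(f), position=np.asarray(p, dtype=float))
        for i, (f, p) in enumerate(zip(frames, positions))
    ]
    return DetectionSet(dets)


def make_net(enter, obs, exit_, transitions, scale=1):
    """Circulation network from integer per-detection costs and a list of
    (i, j, cost) transition triples.  Costs are taken as already quantized
    (scale 1) unless a scale is given."""
    D = len(obs)
    arcs = []
    for i in range(D):
        o, h = 1 + 2 * i, 2 + 2 * i
        arcs.append(Arc(0, o, enter[i] / scale, int(enter[i]), "enter", (i, None)))
        arcs.append(Arc(o, h, obs[i] / scale, int(obs[i]), "observation", (i, None)))
        arcs.append(Arc(h, 0, exit_[i] / scale, int(exit_[i]), "exit", (i, None)))
    for i, j, c in transitions:
        arcs.append(Arc(2 + 2 * i, 1 + 2 * j, c / scale, int(c), "transition", (i, j)))
    return CirculationNetwork(D, arcs, scale)


@pytest.fixture
def single_detection_net():
    """One detection: enter 1, observation -3, exit 1 — the optimum sends
    one unit around the singleton cycle at cost -1."""
    return make_net([1], [-3], [1], [])


@pytest.fixture
def fig1_net():
    """Six detections over three frames (2/2/2) with costs chosen so the
    optimum links detections 0-2-5 as one trajectory, 1-3 as a second and
    leaves 4 as a singleton: three saturated cycles."""
    # frames: 0:{0,1} 1:{2,3} 2:{4,5}
    enter = [2, 2, 2, 2, 2, 2]
    obs = [-5, -5, -5, -5, -5, -5]
    exit_ = [2, 2, 2, 2, 2, 2]
    transitions = [
        (0, 2, -1), (0, 3, 3),
        (1, 2, 3), (1, 3, -1),
        (2, 4, 3), (2, 5, -1),
        (3, 4, 5), (3, 5, 5),
    ]
    return make_net(enter, obs, exit_, transitions)
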