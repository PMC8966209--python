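"""Arc-cost model: closed forms, estimators and gating."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from circtrack.costs import (
    CostConfig,
    boundary_cost,
    detection_cost,
    estimate_rates_from_counts,
    fit_distance_ecdf,
    gate_candidates,
    gt_linkage_cost,
    transition_cost,
)
from circtrack.detections import DetectionSet

from conftest import make_detset


class TestDetectionCost:
    @pytest.mark.parametrize(
        "beta,expected",
        [(0.5, 0.0), (1 / (1 + np.e), -1.0), (0.9, np.log(9.0))],
    )
    def test_closed_form(self, beta, expected):
        assert detection_cost(beta) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("beta", [0.0, 1.0, -1.0, 1.5])
    def test_domain_error(self, beta):
        with pytest.raises(ValueError):
            detection_cost(beta)

    @given(st.floats(0.001, 0.999))
    @settings(deadline=None)
    def test_sign_matches_half(self, beta):
        c = detection_cost(beta)
        assert (c < 0) == (beta < 0.5) and (c == 0) == (beta == 0.5)


class TestBoundaryCost:
    @pytest.mark.parametrize("p,expected", [(1.0, 0.0), (np.exp(-2.0), 2.0)])
    def test_closed_form(self, p, expected):
        assert boundary_cost(p) == pytest.approx(expected, abs=1e-12)

    def test_zero_probability_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            c = boundary_cost(0.0, p_min=1e-9)
        assert c == pytest.approx(-np.log(1e-9))

    @given(st.floats(1e-12, 1.0))
    @settings(deadline=None)
    def test_nonnegative(self, p):
        assert boundary_cost(p) >= 0.0


class TestDistanceECDF:
    def test_survival_convention(self):
        ecdf = fit_distance_ecdf(np.arange(1.0, 11.0))
        assert ecdf.survival(1.0) == 1.0  # min sample: everything >= d
        assert ecdf.survival(10.0) == pytest.approx(0.1)  # only the max
        assert ecdf.survival(8.0) == pytest.approx(0.3)

    def test_out_of_support_clamped(self):
        ecdf = fit_distance_ecdf([5.0])
        assert transition_cost(ecdf, 6.0, p_min=1e-9) == pytest.approx(-np.log(1e-9))

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            fit_distance_ecdf([])


class TestTransitionCost:
    def test_smallest_distance_free(self):
        ecdf = fit_distance_ecdf(np.arange(1.0, 11.0))
        assert transition_cost(ecdf, 1.0) == 0.0

    def test_jump_penalty_is_log_additive(self):
        ecdf = fit_distance_ecdf(np.arange(1.0, 11.0))
        direct = transition_cost(ecdf, 4.0)
        jump = transition_cost(ecdf, 4.0, is_jump=True, p_jump=np.exp(-1.0))
        assert jump - direct == pytest.approx(1.0)

    def test_derived_survival_value(self):
        ecdf = fit_distance_ecdf(np.arange(1.0, 11.0))
        assert transition_cost(ecdf, 8.0) == pytest.approx(-np.log(0.3))

    @given(st.lists(st.floats(0.0, 100.0), min_size=1, max_size=30),
           st.floats(0.0, 120.0), st.floats(0.0, 120.0))
    @settings(deadline=None, max_examples=200)
    def test_monotone_in_distance(self, samples, d1, d2):
        """Transition cost never decreases with distance (fixed ECDF)."""
        ecdf = fit_distance_ecdf(samples)
        lo, hi = sorted((d1, d2))
        assert transition_cost(ecdf, lo) <= transition_cost(ecdf, hi)

    def test_jump_requires_p_jump(self):
        ecdf = fit_distance_ecdf([1.0])
        with pytest.raises(ValueError):
            transition_cost(ecdf, 1.0, is_jump=True, p_jump=None)


class TestRateEstimation:
    def test_hand_counted_mixed(self):
        # counts 10,8,11: births 10 + 3, deaths 2 + 11, total 29
        p_enter, p_exit = estimate_rates_from_counts([10, 8, 11])
        assert p_enter == pytest.approx(13 / 29)
        assert p_exit == pytest.approx(13 / 29)

    def test_constant_counts(self):
        p_enter, p_exit = estimate_rates_from_counts([5, 5, 5])
        assert p_enter == pytest.approx(1 / 3) and p_exit == pytest.approx(1 / 3)

    def test_single_frame_rejected(self):
        with pytest.raises(ValueError):
            estimate_rates_from_counts([7])

    def test_rates_clamped_into_unit_interval(self):
        p_enter, p_exit = estimate_rates_from_counts([1, 1])
        assert 0 < p_enter <= 1 and 0 < p_exit <= 1


class TestGtLinkage:
    def test_negation(self):
        assert gt_linkage_cost(2.0, 3.0) == -5.0
        assert gt_linkage_cost(0.0, 0.0) == 0.0

    def test_singleton_cycle_is_free(self):
        en, ex = boundary_cost(0.3), boundary_cost(0.7)
        assert en + gt_linkage_cost(en, ex) + ex == pytest.approx(0.0)


class TestGating:
    def test_single_chain(self):
        dets = make_detset([0, 1], [[0, 0], [1, 0]])
        cands = gate_candidates(dets, knn=3, jump_window=1)
        assert cands == [(0, 1, 1.0, 1)]

    def test_no_future_frames(self):
        dets = make_detset([0], [[0, 0]])
        assert gate_candidates(dets, knn=3, jump_window=2) == []

    def test_knn_selection_and_tie_break(self):
        # five targets in frame 1; two nearest are at distance 1 (indices 1, 2)
        dets = make_detset(
            [0, 1, 1, 1, 1, 1],
            [[0, 0], [1, 0], [0, 1], [2, 0], [0, 3], [4, 0]],
        )
        cands = gate_candidates(dets, knn=2, jump_window=1)
        assert [(c[0], c[1]) for c in cands] == [(0, 1), (0, 2)]
        # exhaustive check against a brute-force distance sort
        dists = sorted(
            (np.linalg.norm(dets[j].position), j) for j in range(1, 6)
        )
        assert {c[1] for c in cands} == {j for _, j in dists[:2]}

    def test_jump_window_emits_per_gap(self):
        dets = make_detset([0, 1, 2], [[0, 0], [1, 0], [2, 0]])
        cands = gate_candidates(dets, knn=1, jump_window=2)
        assert ((0, 1, 1) in [(c[0], c[1], c[3]) for c in cands])
        assert ((0, 2, 2) in [(c[0], c[1], c[3]) for c in cands])

    def test_input_order_invariance(self):
        """Gating output is a function of the (frame, position) content."""
        rng = np.random.default_rng(5)
        frames = rng.integers(0, 4, size=12)
        pos = rng.uniform(0, 10, size=(12, 2))
        a = DetectionSet.from_arrays(frames, pos)
        perm = rng.permutation(12)
        b = DetectionSet.from_arrays(frames[perm], pos[perm])
        ca = gate_candidates(a, knn=2, jump_window=2)
        cb = gate_candidates(b, knn=2, jump_window=2)
        key = lambda ds, c: (ds[c[0]].frame, tuple(ds[c[0]].position),
                             tuple(ds[c[1]].position), c[3])
        assert sorted(key(a, c) for c in ca) == sorted(key(b, c) for c in cb)


class TestCostConfig:
    def test_round_trips_through_dict(self):
        cfg = CostConfig(p_enter=0.2, knn=5, p_jump=0.3)
        assert CostConfig.from_dict(cfg.to_dict()) == cfg

    @pytest.mark.parametrize(
        "kwargs", [{"p_enter": 0.0}, {"default_beta": 1.0}, {"knn": 0},
                   {"cost_scale": 0}, {"p_jump": 1.5}],
    )
    def test_invalid_fields_rejected(self, kwargs):
        with pytest.raises(ValueError):
            CostConfig(**kwargs)
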