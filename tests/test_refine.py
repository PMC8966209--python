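"""Iterative refinement features and the Frank–Wolfe harness."""

import numpy as np
import pytest

from circtrack.costs import CostConfig
from circtrack.refine import (
    QuadraticObjective,
    estimate_p_jump,
    estimate_velocities,
    frank_wolfe,
    iterate_tracking,
    smooth_velocities,
    track_once,
)
from circtrack.reference import brute_force_solve, random_instance
from circtrack.synthetic import SimulationConfig, simulate
from circtrack.trajectories import Solution, Trajectory

from conftest import make_detset


class TestVelocities:
    def test_straight_line(self):
        dets = make_detset([0, 1, 2], [[0, 0], [1, 0], [2, 0]])
        sol = Solution([Trajectory([0, 1, 2])])
        v = estimate_velocities(sol, dets)
        np.testing.assert_allclose(v, [[1, 0]] * 3)

    def test_singleton_zero(self):
        dets = make_detset([0], [[3, 3]])
        v = estimate_velocities(Solution([Trajectory([0])]), dets)
        np.testing.assert_allclose(v, [[0, 0]])

    def test_gap_link_divides_by_gap(self):
        dets = make_detset([0, 2], [[0, 0], [2, 2]])
        v = estimate_velocities(Solution([Trajectory([0, 1])]), dets)
        np.testing.assert_allclose(v, [[1, 1], [1, 1]])

    def test_unlinked_detections_zero(self):
        dets = make_detset([0, 0], [[0, 0], [5, 5]])
        v = estimate_velocities(Solution([Trajectory([0])]), dets)
        np.testing.assert_allclose(v[1], [0, 0])


class TestSmoothing:
    def test_outlier_calibrated_by_neighbors(self):
        dets = make_detset([0] * 5, [[0, 0], [1, 0], [0, 1], [1, 1], [0.5, 0.5]])
        v = np.array([[1.0, 0.0]] * 4 + [[9.0, 9.0]])
        out = smooth_velocities(v, dets)
        np.testing.assert_allclose(out[4], [1.0, 0.0])

    def test_uniform_velocities_unchanged(self):
        dets = make_detset([0] * 5, [[i, 0] for i in range(5)])
        v = np.tile([2.0, -1.0], (5, 1))
        np.testing.assert_allclose(smooth_velocities(v, dets), v)

    def test_lone_detection_unchanged(self):
        dets = make_detset([0, 1], [[0, 0], [1, 1]])
        v = np.array([[3.0, 3.0], [4.0, 4.0]])
        np.testing.assert_allclose(smooth_velocities(v, dets), v)


class TestPJump:
    def test_fraction(self):
        dets = make_detset(list(range(11)), [[i, 0] for i in range(11)])
        # one chain with 10 links, 2 of them jumps: frames 0..7,9,...? build
        # explicitly: chain over frames 0-10 skipping 3 and 7
        frames = [0, 1, 2, 4, 5, 6, 8, 9, 10]
        dets = make_detset(frames, [[f, 0] for f in frames])
        sol = Solution([Trajectory(list(range(9)))])
        assert estimate_p_jump(sol, dets) == pytest.approx(2 / 8)

    def test_no_links_gives_floor(self):
        dets = make_detset([0], [[0, 0]])
        sol = Solution([Trajectory([0])])
        assert estimate_p_jump(sol, dets, p_min=1e-9) == 1e-9

    def test_all_jumps(self):
        dets = make_detset([0, 2, 4], [[0, 0], [2, 0], [4, 0]])
        sol = Solution([Trajectory([0, 1, 2])])
        assert estimate_p_jump(sol, dets) == 1.0


class TestIterateTracking:
    def test_single_iteration_is_plain_pipeline(self):
        dets, _ = simulate(SimulationConfig(
            n_objects_init=6, n_frames=8, arena=(80.0, 80.0),
            speed_scale=1.0, noise_sigma=0.1, seed=21))
        cfg = CostConfig(use_gt_linkage=True)
        states = iterate_tracking(dets, cfg, n_iterations=1)
        sol, _, _ = track_once(dets, cfg)
        assert [t.detections for t in states[0].solution.trajectories] == \
            [t.detections for t in sol.trajectories]

    def test_disabled_refinements_reproduce_plain_pipeline_exactly(self):
        """With velocity gating and every refit switched off, iteration 2
        rebuilds the identical network and returns the same solution."""
        dets, _ = simulate(SimulationConfig(
            n_objects_init=8, n_frames=10, arena=(60.0, 60.0),
            speed_scale=1.0, miss_rate=0.1, noise_sigma=0.1, seed=33))
        states = iterate_tracking(
            dets, CostConfig(use_gt_linkage=True), n_iterations=2,
            refit_ecdf=False, refit_rates=False, refit_p_jump=False,
            use_velocity=False)
        assert [t.detections for t in states[0].solution.trajectories] == \
            [t.detections for t in states[1].solution.trajectories]
        assert states[0].solution.total_cost_int == \
            states[1].solution.total_cost_int

    def test_refinement_reduces_switches_in_fast_coherent_flow(self):
        """When per-frame displacement exceeds the object spacing, distance
        linking shuffles identities; velocity-predicted gating recovers
        them (seed-averaged)."""
        ids1, ids2 = [], []
        for seed in range(4):
            dets, gt = simulate(SimulationConfig(
                n_objects_init=20, n_frames=12, arena=(45.0, 45.0),
                motion="constant_velocity", speed_scale=4.0,
                velocity_groups=2, noise_sigma=0.1, seed=600 + seed))
            states = iterate_tracking(
                dets, CostConfig(use_gt_linkage=True), n_iterations=2)
            from circtrack.trajectories import evaluate
            reps = [evaluate(st.solution, gt.ids, gt.frames, gt.positions,
                             dets, 3.0) for st in states]
            ids1.append(reps[0].ids)
            ids2.append(reps[1].ids)
        assert np.mean(ids2) < np.mean(ids1)


class TestFrankWolfe:
    def test_step_size_schedule(self, fig1_net):
        obj = QuadraticObjective(fig1_net.int_costs().astype(float),
                                 np.zeros((fig1_net.n_arcs,) * 2))
        _, _, _, gammas = frank_wolfe(obj, fig1_net, n_iterations=3)
        assert gammas == pytest.approx([1 / 3, 1 / 2, 3 / 5])

    def test_zero_quadratic_reproduces_plain_optimum(self, fig1_net):
        c = fig1_net.int_costs().astype(float)
        obj = QuadraticObjective(c, np.zeros((fig1_net.n_arcs,) * 2))
        x, x_int, trace, _ = frank_wolfe(obj, fig1_net, n_iterations=1)
        assert c @ x_int == brute_force_solve(fig1_net).optimal_cost

    def test_positive_definite_trace_decreases(self, fig1_net):
        m = fig1_net.n_arcs
        rng = np.random.default_rng(0)
        q = rng.normal(size=(m, m)) * 0.1
        Q = q @ q.T + 0.01 * np.eye(m)
        obj = QuadraticObjective(fig1_net.int_costs().astype(float), Q)
        _, _, trace, _ = frank_wolfe(obj, fig1_net, n_iterations=8)
        assert trace[-1] <= trace[0]

    def test_iterates_are_feasible_fractional_circulations(self, fig1_net):
        """Every iterate is a convex combination of circulations: bounded
        in [0,1] and conserving at every node."""
        m = fig1_net.n_arcs
        obj = QuadraticObjective(fig1_net.int_costs().astype(float),
                                 0.01 * np.eye(m))
        x, _, _, _ = frank_wolfe(obj, fig1_net, n_iterations=5)
        assert (x >= -1e-9).all() and (x <= 1 + 1e-9).all()
        balance = np.zeros(fig1_net.n_nodes)
        for k, a in enumerate(fig1_net.arcs):
            balance[a.tail] += x[k]
            balance[a.head] -= x[k]
        np.testing.assert_allclose(balance, 0, atol=1e-9)

    def test_asymmetric_quadratic_rejected(self, fig1_net):
        m = fig1_net.n_arcs
        Q = np.zeros((m, m))
        Q[0, 1] = 1.0
        with pytest.raises(ValueError, match="symmetric"):
            QuadraticObjective(np.zeros(m), Q)

    def test_dimension_mismatch_rejected(self, fig1_net):
        obj = QuadraticObjective(np.zeros(3), np.zeros((3, 3)))
        with pytest.raises(ValueError, match="dimension"):
            frank_wolfe(obj, fig1_net)
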