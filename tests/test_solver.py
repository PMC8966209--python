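"""Cost-scaling circulation solver: optimality, invariants, operations."""

import numpy as np
import pytest

from circtrack.network import assert_structure
from circtrack.reference import brute_force_solve, random_instance, ssp_solve
from circtrack.solver import SolverState, solve
from circtrack.trajectories import flow_to_trajectories

from conftest import make_net


class TestSolveBasics:
    def test_all_nonnegative_costs_zero_flow(self):
        """With no negative arc no cycle pays: zero flow, zero cost."""
        net = make_net([1, 2], [3, 0], [1, 1], [(0, 1, 2)])
        flow, cost, _ = solve(net)
        assert cost == 0 and not flow.any()

    def test_single_detection_negative_cycle(self, single_detection_net):
        """Both feasible circulations enumerated by hand: the saturated
        singleton cycle (cost -1) beats the empty one (cost 0)."""
        flow, cost, _ = solve(single_detection_net)
        assert cost == -1
        assert flow.tolist() == [1, 1, 1]

    def test_fig1_three_chains(self, fig1_net):
        """Topology with two detections per frame and costs that make three
        trajectories optimal, one of them linking detections 0, 2, 5."""
        flow, cost, _ = solve(fig1_net)
        assert cost == brute_force_solve(fig1_net).optimal_cost
        sol = flow_to_trajectories(fig1_net, flow)
        chains = sorted(tuple(t.detections) for t in sol.trajectories)
        assert chains == [(0, 2, 5), (1, 3), (4,)]

    def test_empty_network(self):
        net = make_net([], [], [], [])
        flow, cost, state = solve(net)
        assert cost == 0 and flow.size == 0


class TestOracleAgreement:
    @pytest.mark.parametrize("tier,seeds", [("small", range(40)),
                                            ("medium", range(40, 50))])
    def test_three_way_equivalence(self, tier, seeds):
        """solver == SSP == brute force on random instances, exactly."""
        checked = 0
        for seed in seeds:
            net = random_instance(seed, tier)
            if net is None:
                continue
            _, cost, _ = solve(net)
            assert cost == ssp_solve(net).optimal_cost
            assert cost == brute_force_solve(net).optimal_cost
            checked += 1
        assert checked >= 5


class TestSolverInvariants:
    def _solved_states(self, n=15):
        states = []
        for seed in range(200, 200 + 2 * n):
            net = random_instance(seed, "small")
            if net is None:
                continue
            _, _, st = solve(net)
            states.append((net, st))
            if len(states) == n:
                break
        return states

    def test_eps_optimality_every_phase(self):
        for _, st in self._solved_states():
            assert all(e["eps_optimal"] for e in st.stats.phase_log)

    def test_terminal_feasibility_and_optimality_certificate(self):
        for net, st in self._solved_states():
            assert not st.excess.any()
            assert st.check_eps_optimality(1, all_arcs=True)

    def test_phase_count_bound(self):
        for net, st in self._solved_states():
            C = max(net.max_abs_cost(), 1)
            bound = int(np.ceil(np.log2(net.n_nodes * C))) + 2
            assert st.stats.phases <= bound

    def test_push_cap_respected(self):
        for _, st in self._solved_states():
            assert st.stats.max_pushes_per_pass <= st.push_cap

    def test_flow_decomposes_into_cycles_through_s(self):
        for net, st in self._solved_states():
            sol = flow_to_trajectories(net, st.flow())
            assert sol.flow_amount == sum(
                st.flow()[k] for k, a in enumerate(net.arcs) if a.kind == "enter"
            )

    def test_determinism(self):
        net = random_instance(7, "small")
        f1, c1, _ = solve(net)
        f2, c2, _ = solve(net)
        assert c1 == c2 and np.array_equal(f1, f2)


class TestOperations:
    def _stuck_state(self):
        """1-detection network, all-zero costs, with a manufactured excess
        at the pre-node and deficit at the post-node."""
        net = make_net([0], [0], [0], [])
        st = SolverState(net)
        st.epsilon = 4
        o, h = net.pre_node(0), net.post_node(0)
        st.excess[o], st.excess[h] = 1, -1
        return net, st, o, h

    def test_saturate_admissible_bookkeeping(self):
        net = make_net([1], [-3], [1], [])
        st = SolverState(net)
        st.epsilon = st.eps0 // 2
        st.saturate_admissible()
        # only the negative observation arc is admissible at p = 0
        o, h = net.pre_node(0), net.post_node(0)
        assert st.excess[o] == -1 and st.excess[h] == 1
        assert st.resid[2] == 0 and st.resid[3] == 1  # obs arc saturated
        # postcondition: no admissible residual arc remains
        assert all(
            st.reduced_cost(a) >= 0
            for a in range(2 * st.m) if st.resid[a] > 0
        )

    def test_saturate_no_admissible_is_noop(self):
        net = make_net([1], [2], [3], [])
        st = SolverState(net)
        st.epsilon = st.eps0 // 2
        before = st.resid.copy()
        st.saturate_admissible()
        assert np.array_equal(st.resid, before) and not st.excess.any()

    def test_set_relabel_single_raise_connects(self):
        """Excess node with a zero-reduced-cost arc to a deficit: one
        ε-raise of the deficit makes the arc admissible."""
        net, st, o, h = self._stuck_state()
        prices_before = st.price.copy()
        marked = st.set_relabel()
        assert st.price[h] == prices_before[h] + st.epsilon
        assert (st.price >= prices_before).all()  # monotone
        # the arc o -> h is now admissible and marked as blocking direction
        assert marked[2]

    def test_push_relabel_balances_excess_deficit_pair(self):
        net, st, o, h = self._stuck_state()
        marked = st.set_relabel()
        st.push_relabel_pass(marked)
        assert not st.excess.any()

    def test_relabel_applied_to_stuck_excess_node(self):
        """An excess node with no admissible out-arc (and no admissible
        in-arc) is relabeled by exactly ε, then re-examined."""
        net = make_net([0], [0], [0], [])
        st = SolverState(net)
        st.epsilon = 4
        h = net.post_node(0)
        st.excess[h], st.excess[0] = 1, -1  # excess at post-node, deficit at s
        p_before = int(st.price[h])
        st.push_relabel_pass()  # (h, s) has reduced cost 0: not admissible
        assert st.price[h] == p_before + st.epsilon
        assert st.stats.relabels == 1

    def test_restore_noop_when_feasible(self, single_detection_net):
        st = SolverState(single_detection_net)
        st.epsilon = st.eps0
        st.restore()
        assert st.stats.restore_passes == 0

    def test_price_refinement_never_changes_flow(self):
        net = random_instance(11, "small")
        st = SolverState(net)
        st.epsilon = st.eps0 // 2
        st.saturate_admissible()
        st.restore()
        flow_before = st.flow().copy()
        excess_before = st.excess.copy()
        ok = st.price_refinement()
        assert np.array_equal(st.flow(), flow_before)
        assert np.array_equal(st.excess, excess_before)
        if ok:
            assert st.check_eps_optimality(st.epsilon // 2, all_arcs=False)

    def test_price_refinement_false_on_admissible_cycle(self):
        # zero flow, negative costs all around the singleton cycle: the
        # admissible network contains the cycle s -> o -> h -> s
        net = make_net([-2], [-2], [-2], [])
        st = SolverState(net)
        st.epsilon = 4
        assert st._admissible_has_cycle()
        assert st.price_refinement() is False

    def test_check_eps_optimality_verifier(self):
        net = make_net([1], [-3], [1], [])
        st = SolverState(net)
        assert st.check_eps_optimality(st.eps0)  # zero flow, |c| <= C
        assert not st.check_eps_optimality(0)  # the -3 arc violates eps=0


class TestArcFixing:
    def test_fixing_matches_unfixed_optimum(self):
        """Arc fixing is a scan-set optimization only: identical optima."""
        checked = 0
        for seed in range(300, 360):
            net = random_instance(seed, "small")
            if net is None or net.n_detections == 0:
                continue
            _, c_off, _ = solve(net)
            _, c_on, st = solve(net, fix_threshold=2.0)
            assert c_on == c_off
            assert st.check_eps_optimality(1, all_arcs=True)
            checked += 1
        assert checked >= 20

    def test_infinite_threshold_identical(self):
        net = random_instance(3, "small")
        f1, c1, _ = solve(net)
        f2, c2, _ = solve(net, fix_threshold=float("inf"))
        assert c1 == c2 and np.array_equal(f1, f2)
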