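import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from syncpath import (
    WeightedGraph,
    cluster_census,
    detect_transition,
    e_matrix,
    eigendecompose,
    equitable_cells,
    plan_from_json,
    plan_to_json,
    rotate_degenerate_basis,
    s_matrix_at,
    scale_plan,
    verify_plan,
)
from syncpath.msf import LyapunovSettings, MSFClassification, MSFCurve
from syncpath.transition import ClusterEvent, TransitionPlan

from conftest import adjacency
from test_graphs import random_connected_graph


def events_summary(plan):
    return [
        (e.event_type, tuple(sorted(e.nodes, key=int)), round(e.relative_coupling, 9))
        for e in plan.events
    ]


class TestEMatrix:
    def test_trivial_eigenvector_gives_zero(self, f4):
        spec = eigendecompose(f4)
        np.testing.assert_allclose(e_matrix(spec, 1), 0.0, atol=1e-12)

    def test_f4_fiedler_entries(self, f4):
        # the lambda=2 eigenvector is (e1 - e2)/sqrt(2) up to sign
        spec = eigendecompose(f4)
        e = e_matrix(spec, 2)
        assert e[0, 1] == pytest.approx(2.0, abs=1e-10)
        assert e[2, 3] == pytest.approx(0.0, abs=1e-10)

    @given(st.integers(0, 300))
    @settings(max_examples=15, deadline=None)
    def test_matches_brute_force_double_loop(self, seed):
        g = random_connected_graph(seed, n_max=8)
        spec = eigendecompose(g)
        n = g.n_nodes
        i = int(np.random.default_rng(seed).integers(1, n + 1))
        e = e_matrix(spec, i)
        v = spec.vectors[:, i - 1]
        for j in range(n):
            for k in range(n):
                assert e[j, k] == pytest.approx((v[j] - v[k]) ** 2, abs=1e-12)

    def test_index_out_of_range(self, f4):
        spec = eigendecompose(f4)
        with pytest.raises(IndexError):
            e_matrix(spec, 0)
        with pytest.raises(IndexError):
            e_matrix(spec, 5)


class TestSMatrix:
    def test_s2_off_diagonals_all_two(self, demo10_spectrum):
        s = s_matrix_at(demo10_spectrum, 2)
        off = s[~np.eye(demo10_spectrum.n, dtype=bool)]
        np.testing.assert_allclose(off, 2.0, atol=1e-8)

    def test_f4_block_boundary_entries(self, f4):
        spec = eigendecompose(f4)
        s3 = s_matrix_at(spec, 3)  # the lambda=4 block summed
        assert s3[2, 3] == pytest.approx(2.0, abs=1e-10)
        assert s3[0, 1] == pytest.approx(0.0, abs=1e-10)

    @given(st.integers(0, 300))
    @settings(max_examples=15, deadline=None)
    def test_recursion_identity_and_monotonicity(self, seed):
        g = random_connected_graph(seed, n_max=9)
        spec = eigendecompose(g)
        n = g.n_nodes
        for m in range(1, n):
            s_m, s_next = s_matrix_at(spec, m), s_matrix_at(spec, m + 1)
            np.testing.assert_allclose(s_m - s_next, e_matrix(spec, m), atol=1e-10)
            assert np.all(s_m - s_next >= -1e-12)  # entrywise nonincreasing in n
        full = s_matrix_at(spec, 1)
        assert np.all(full <= 2.0 + 1e-9)


class TestDetectTransition:
    def test_f4_formation_then_complete(self, f4):
        plan = detect_transition(eigendecompose(f4))
        assert events_summary(plan) == [
            ("formation", ("3", "4"), 0.25),
            ("complete", ("1", "2", "3", "4"), 0.5),
        ]

    def test_complete_graph_single_event(self, k4):
        plan = detect_transition(eigendecompose(k4))
        assert events_summary(plan) == [("complete", ("1", "2", "3", "4"), 0.25)]

    def test_three_orbit_demo_event_pattern(self, demo10_spectrum):
        plan = detect_transition(demo10_spectrum)
        assert events_summary(plan) == [
            ("formation", ("7", "8", "9", "10"), round(1 / 6, 9)),
            ("growth", ("4", "5", "6", "7", "8", "9", "10"), 0.25),
            ("complete", tuple(str(i) for i in range(1, 11)), 1.0),
        ]
        growth = plan.events[1]
        assert growth.merged_from == (frozenset({"7", "8", "9", "10"}),)

    def test_path_graph_outer_cell_locks_only_at_global_threshold(self, p3):
        # {1,3} is an equitable cell of the path, but its pair entry first
        # reaches 2 at S_2, so no event precedes complete synchronization
        plan = detect_transition(eigendecompose(p3))
        assert events_summary(plan) == [("complete", ("1", "2", "3"), 1.0)]

    @pytest.mark.parametrize("rot_seed", [0, 1])
    def test_basis_rotation_invariance(self, demo10_spectrum, k4, rot_seed):
        for spec in (demo10_spectrum, eigendecompose(k4)):
            rotated = rotate_degenerate_basis(spec, seed=rot_seed)
            assert events_summary(detect_transition(rotated)) == events_summary(
                detect_transition(spec)
            )

    def test_planted_clusters_match_ground_truth(self, planted_small, planted_medium):
        for pg in (planted_small, planted_medium):
            plan = detect_transition(eigendecompose(pg.graph))
            found = {frozenset(e.nodes) for e in plan.cluster_events()}
            assert found == set(pg.expected_eigenvalues)
            for event in plan.cluster_events():
                val, _ = pg.expected_eigenvalues[frozenset(event.nodes)]
                assert event.block_eigenvalue == pytest.approx(val, abs=1e-9)

    def test_final_event_covers_all_nodes_at_lambda2(self, planted_medium):
        spec = eigendecompose(planted_medium.graph)
        plan = detect_transition(spec)
        final = plan.complete_event
        assert final.nodes == frozenset(planted_medium.graph.node_labels)
        assert final.block_eigenvalue == pytest.approx(spec.lambda2)


def _class_iii(nu1, nu2):
    curve = MSFCurve(
        np.array([0.0, nu1 / 2, (nu1 + nu2) / 2, 2 * nu2]),
        np.array([1.0, 0.5, -1.0, 1.0]),
        LyapunovSettings(),
    )
    return MSFClassification("III", curve, nu1_star=nu1, nu2_star=nu2)


class TestScalePlan:
    def test_demo_graph_rossler_and_lorenz_thresholds(self, demo10_spectrum):
        plan = detect_transition(demo10_spectrum)
        for nu_star, expected in [
            (0.179, [0.0298333, 0.04475, 0.179]),
            (7.322, [1.2203333, 1.8305, 7.322]),
        ]:
            scaled = scale_plan(plan, nu_star)
            got = [e.absolute_coupling for e in scaled.events]
            np.testing.assert_allclose(got, expected, rtol=1e-5)
            assert all(e.reachable for e in scaled.events)

    def test_class_iii_flags_unreachable_events(self, f4):
        # F4 events at lambda = 4 (d = nu1/4) and lambda = 2 (d = nu1/2);
        # with nu2/lambda_N below nu1/2 the complete event is out of reach
        plan = detect_transition(eigendecompose(f4))
        scaled = scale_plan(plan, _class_iii(1.0, 1.5))
        assert scaled.events[0].absolute_coupling == pytest.approx(0.25)
        assert scaled.events[0].reachable  # 0.25 < 1.5/4
        assert not scaled.events[-1].reachable  # 0.5 >= 0.375

    def test_class_i_and_nonpositive_intercepts_rejected(self, f4):
        plan = detect_transition(eigendecompose(f4))
        curve = MSFCurve(np.array([0.0, 1.0]), np.array([1.0, 0.5]), LyapunovSettings())
        with pytest.raises(ValueError, match="Class I"):
            scale_plan(plan, MSFClassification("I", curve))
        with pytest.raises(ValueError, match="positive"):
            scale_plan(plan, 0.0)


class TestEquitableCells:
    def test_f4_cells(self, f4):
        cells = equitable_cells(f4)
        assert set(cells.nontrivial()) == {frozenset({"1", "2"}), frozenset({"3", "4"})}

    def test_path_graph_outer_cell(self, p3):
        cells = equitable_cells(p3)
        assert set(cells.nontrivial()) == {frozenset({"1", "3"})}
        assert cells.cell_of("2") == frozenset({"2"})

    def test_distinct_weights_give_singletons(self):
        a = adjacency(4, [(0, 1, 1.0), (1, 2, 2.0), (2, 3, 3.0)])
        g = WeightedGraph(["1", "2", "3", "4"], a)
        assert equitable_cells(g).nontrivial() == []

    def test_planted_cells_recovered(self, planted_medium):
        cells = equitable_cells(planted_medium.graph)
        assert set(cells.nontrivial()) == set(planted_medium.expected_eigenvalues)


class TestVerifyPlan:
    def test_valid_plan_passes(self, f4, demo10, demo10_spectrum):
        assert verify_plan(detect_transition(eigendecompose(f4)), f4).ok
        assert verify_plan(detect_transition(demo10_spectrum), demo10).ok

    def test_corrupted_event_reported(self, f4):
        plan = detect_transition(eigendecompose(f4))
        bad = TransitionPlan(
            events=[
                ClusterEvent(
                    nodes=frozenset({"1", "3"}),  # not a cell of F4
                    block_eigenvalue=4.0,
                    relative_coupling=0.25,
                    event_type="formation",
                ),
                plan.events[-1],
            ],
            node_labels=plan.node_labels,
        )
        report = verify_plan(bad, f4)
        assert not report.ok
        assert report.violations[0].event_nodes == frozenset({"1", "3"})


class TestCensusAndJson:
    def test_census_counts_planted_clusters(self, planted_medium):
        plan = detect_transition(eigendecompose(planted_medium.graph))
        census = cluster_census(plan, planted_medium.graph)
        assert census["n_clusters"] == 2
        assert census["n_clustered_nodes"] == 12
        assert census["size_histogram"] == {8: 1, 4: 1}

    def test_plan_json_round_trip(self, demo10_spectrum):
        plan = scale_plan(detect_transition(demo10_spectrum), 0.179)
        back = plan_from_json(plan_to_json(plan))
        assert events_summary(back) == events_summary(plan)
        assert [e.absolute_coupling for e in back.events] == [
            e.absolute_coupling for e in plan.events
        ]
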