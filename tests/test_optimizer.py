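"""Anchored placement solvers: closed forms, oracles, invariants."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from wireopt import (
    DisconnectedFreeComponentError,
    NormSpec,
    PlacementProblem,
    build_weights,
    solve,
    solve_l1,
    solve_power_p,
    solve_squared_l2,
    solve_weber_l2,
    solve_with_min_distance,
    total_wiring_length,
    weighted_median,
)

from _oracles import block_grid_descent, grid_search_objective
from conftest import make_problem

ALL_SPECS = [
    NormSpec.l1(),
    NormSpec.l2(),
    NormSpec.squared_l2(),
    NormSpec.euclidean_power(3),
    NormSpec.euclidean_power(4),
]


def _worm_problem(worm_instance, spec):
    from wireopt import WeightScheme

    table, conn = worm_instance
    w = build_weights(conn, WeightScheme.unit_joint())
    return table, PlacementProblem(w, table.fixed_mask, table.coords, spec)


# ---------------------------------------------------------------------------
# squared Euclidean cost


class TestSquaredL2:
    def test_midpoint_of_equal_anchors(self):
        W = np.zeros((3, 3))
        W[2, 0] = W[2, 1] = 1.0
        coords = np.array([[0.0, 0.0], [2.0, 0.0], [5.0, 5.0]])
        prob = make_problem(W, [True, True, False], coords, NormSpec.squared_l2())
        sol = solve_squared_l2(prob)
        np.testing.assert_allclose(sol.layout[2], [1.0, 0.0], atol=1e-12)
        assert sol.objective == pytest.approx(2.0, rel=1e-12)

    def test_weighted_average_closed_form(self, single_free_two_anchors):
        W, fixed, coords = single_free_two_anchors
        prob = make_problem(W, fixed, coords, NormSpec.squared_l2())
        sol = solve_squared_l2(prob)
        # x* = (1*0 + 3*3) / 4 = 2.25
        np.testing.assert_allclose(sol.layout[2], [2.25, 0.0], atol=1e-12)

    def test_chain_two_free_hand_solved(self):
        # anchors (0,0),(3,0); chain a-f1-f2-b, unit weights
        # stationarity: 2 x1 = 0 + x2 ; 2 x2 = x1 + 3  ->  x1 = 1, x2 = 2
        W = np.zeros((4, 4))
        W[0, 2] = W[2, 3] = W[3, 1] = 1.0
        coords = np.array([[0.0, 0.0], [3.0, 0.0], [0.5, 1.0], [0.5, -1.0]])
        prob = make_problem(W, [True, True, False, False], coords,
                            NormSpec.squared_l2())
        sol = solve_squared_l2(prob)
        np.testing.assert_allclose(sol.layout[2], [1.0, 0.0], atol=1e-10)
        np.testing.assert_allclose(sol.layout[3], [2.0, 0.0], atol=1e-10)

    def test_stationarity_residual(self, worm_instance):
        table, prob = _worm_problem(worm_instance, NormSpec.squared_l2())
        sol = solve_squared_l2(prob)
        s = prob.sym_weights
        scale = np.ptp(table.coords)
        for i in prob.free_idx:
            deg = s[i].sum()
            if deg == 0:
                continue
            resid = np.linalg.norm(deg * sol.layout[i] - s[i] @ sol.layout)
            assert resid <= 1e-9 * deg * scale

    def test_fixed_rows_bit_identical(self, worm_instance):
        table, prob = _worm_problem(worm_instance, NormSpec.squared_l2())
        sol = solve_squared_l2(prob)
        fixed = prob.fixed_mask
        assert np.array_equal(sol.layout[fixed], prob.coords[fixed])

    def test_objective_consistent_with_metric(self, worm_instance):
        _, prob = _worm_problem(worm_instance, NormSpec.squared_l2())
        sol = solve_squared_l2(prob)
        recomputed = total_wiring_length(sol.layout, prob.weights, prob.spec)
        assert sol.objective == pytest.approx(recomputed, rel=1e-9)

    def test_disconnected_free_component_raises(self):
        # two free nodes wired only to each other: translation-invariant
        W = np.zeros((3, 3))
        W[1, 2] = 1.0
        coords = np.zeros((3, 2))
        prob = make_problem(W, [True, False, False], coords,
                            NormSpec.squared_l2())
        with pytest.raises(DisconnectedFreeComponentError):
            solve_squared_l2(prob)

    def test_isolated_free_node_kept_and_warned(self):
        W = np.zeros((3, 3))
        W[1, 0] = 1.0  # node 2 has no edges at all
        coords = np.array([[0.0, 0.0], [1.0, 1.0], [9.0, 9.0]])
        prob = make_problem(W, [True, False, False], coords,
                            NormSpec.squared_l2())
        with pytest.warns(UserWarning, match="no connections"):
            sol = solve_squared_l2(prob)
        np.testing.assert_array_equal(sol.layout[2], [9.0, 9.0])
        assert sol.diagnostics["isolated_free"] == [2]


# ---------------------------------------------------------------------------
# Euclidean cost (multifacility Weber)


class TestWeberL2:
    def test_equilateral_triangle_fermat_point(self):
        tri = np.array([[0.0, 0.0], [1.0, 0.0], [0.5, np.sqrt(3) / 2]])
        W = np.zeros((4, 4))
        W[3, :3] = 1.0
        coords = np.vstack([tri, [0.1, 0.9]])
        prob = make_problem(W, [True, True, True, False], coords, NormSpec.l2())
        sol = solve_weber_l2(prob)
        np.testing.assert_allclose(sol.layout[3], tri.mean(axis=0), atol=1e-7)
        assert sol.converged

    def test_degenerate_collinear_objective(self):
        # two equal anchors: every point on the segment is optimal, so only
        # the objective (= inter-anchor distance) is asserted
        W = np.zeros((3, 3))
        W[2, 0] = W[2, 1] = 1.0
        coords = np.array([[0.0, 0.0], [4.0, 0.0], [1.0, 3.0]])
        prob = make_problem(W, [True, True, False], coords, NormSpec.l2())
        sol = solve_weber_l2(prob)
        assert sol.objective == pytest.approx(4.0, abs=1e-7)

    def test_matches_grid_oracle_three_free(self):
        rng = np.random.default_rng(7)
        n = 8  # 5 anchors + 3 free
        coords = rng.uniform(0, 1, size=(n, 2))
        W = rng.random((n, n)) * (rng.random((n, n)) < 0.6)
        np.fill_diagonal(W, 0.0)
        W[5:, 5:] *= 0.15  # mild coupling: optimum stays non-degenerate
        fixed = np.array([True] * 5 + [False] * 3)
        prob = make_problem(W, fixed, coords, NormSpec.l2())
        sol = solve_weber_l2(prob)
        oracle_obj, _ = block_grid_descent(prob, -0.5, 1.5, sweeps=100)
        assert sol.objective == pytest.approx(oracle_obj, abs=1e-3)
        assert sol.objective <= oracle_obj + 1e-6  # solver at least as good

    def test_strong_coupling_collapses_free_nodes(self):
        # strong mutual attraction drives all free nodes coincident; the
        # optimum then equals a single Weber point with pooled weights,
        # which a one-variable grid search verifies independently
        rng = np.random.default_rng(7)
        n = 8
        coords = rng.uniform(0, 1, size=(n, 2))
        W = rng.random((n, n)) * (rng.random((n, n)) < 0.6)
        np.fill_diagonal(W, 0.0)
        fixed = np.array([True] * 5 + [False] * 3)
        prob = make_problem(W, fixed, coords, NormSpec.l2())
        sol = solve_weber_l2(prob)
        assert np.ptp(sol.layout[5:], axis=0).max() < 1e-6

        s = W + W.T
        pooled = np.zeros((6, 6))
        pooled[5, :5] = s[5:, :5].sum(axis=0)
        collapsed = make_problem(
            pooled,
            np.array([True] * 5 + [False]),
            np.vstack([coords[:5], coords[5]]),
            NormSpec.l2(),
        )
        anchor_cost = float(
            np.sum(W[:5, :5] * np.linalg.norm(
                coords[:5, None] - coords[None, :5], axis=-1))
        )
        # the collapsed problem carries no anchor-anchor cost; add it back
        collapsed_opt = grid_search_objective(collapsed, -0.5, 1.5)
        assert sol.objective == pytest.approx(collapsed_opt + anchor_cost,
                                              abs=1e-3)


# ---------------------------------------------------------------------------
# l1 cost


class TestWeightedMedian:
    def test_median_of_three(self):
        assert weighted_median([0.0, 1.0, 10.0], [1, 1, 1]) == 1.0

    def test_majority_weight_side(self):
        assert weighted_median([0.0, 10.0], [3, 1]) == 0.0

    def test_tied_interval_midpoint(self):
        assert weighted_median([0.0, 10.0], [1, 1]) == 5.0

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(-50, 50), min_size=1, max_size=8),
        st.data(),
    )
    def test_minimizes_weighted_absolute_deviation(self, values, data):
        weights = data.draw(
            st.lists(st.floats(0.1, 5), min_size=len(values),
                     max_size=len(values))
        )
        v = np.array(values)
        w = np.array(weights)
        m = weighted_median(v, w)

        def cost(x):
            return float((w * np.abs(x - v)).sum())

        # candidate minimizers of a 1-D weighted L1 cost are the data points
        best = min(cost(x) for x in v)
        assert cost(m) <= best + 1e-9 * max(1.0, best)


class TestL1Solver:
    def test_single_node_per_coordinate_median(self):
        # anchors at x in {0, 1, 10}, unit weights -> x* = 1 per coordinate
        W = np.zeros((4, 4))
        W[3, :3] = 1.0
        coords = np.array([[0.0, 0.0], [1.0, 1.0], [10.0, 10.0], [5.0, 5.0]])
        prob = make_problem(W, [True, True, True, False], coords, NormSpec.l1())
        sol = solve_l1(prob)
        np.testing.assert_allclose(sol.layout[3], [1.0, 1.0], atol=1e-12)

    def test_majority_weight_anchor(self, single_free_two_anchors):
        W, fixed, coords = single_free_two_anchors
        prob = make_problem(W, fixed, coords, NormSpec.l1())
        sol = solve_l1(prob)
        np.testing.assert_allclose(sol.layout[2], [3.0, 0.0], atol=1e-9)

    def test_separability_joint_equals_per_axis(self, worm_instance):
        table, prob = _worm_problem(worm_instance, NormSpec.l1())
        sol = solve_l1(prob)
        # solving with all y-coordinates collapsed must reproduce the same
        # x-solution: the axes are independent problems
        coords_x = prob.coords.copy()
        coords_x[:, 1] = 0.0
        prob_x = dataclasses.replace(prob, coords=coords_x)
        sol_x = solve_l1(prob_x)
        np.testing.assert_allclose(
            sol.layout[prob.free_idx, 0], sol_x.layout[prob.free_idx, 0],
            atol=1e-6,
        )

    def test_coupled_instance_matches_grid_oracle(self):
        rng = np.random.default_rng(3)
        coords = rng.uniform(0, 1, size=(6, 2))
        W = np.zeros((6, 6))
        W[4, 0] = W[4, 1] = 1.0
        W[5, 2] = W[5, 3] = 2.0
        W[4, 5] = 1.5  # free-free coupling
        fixed = np.array([True] * 4 + [False] * 2)
        prob = make_problem(W, fixed, coords, NormSpec.l1())
        sol = solve_l1(prob)
        oracle = grid_search_objective(prob, -0.5, 1.5)
        assert sol.objective == pytest.approx(oracle, abs=1e-3)
        assert sol.objective <= oracle + 1e-9


# ---------------------------------------------------------------------------
# Euclidean powers p = 2, 3, 4


class TestPowerP:
    @pytest.mark.parametrize("p", [2, 3, 4])
    def test_symmetric_anchor_pair_midpoint(self, p):
        W = np.zeros((3, 3))
        W[2, 0] = W[2, 1] = 1.0
        coords = np.array([[0.0, 0.0], [2.0, 2.0], [3.0, -1.0]])
        prob = make_problem(W, [True, True, False], coords,
                            NormSpec.euclidean_power(p))
        sol = solve_power_p(prob)
        np.testing.assert_allclose(sol.layout[2], [1.0, 1.0], atol=1e-6)

    def test_p2_consistent_with_exact_linear_solve(self, worm_instance):
        _, prob = _worm_problem(worm_instance, NormSpec.squared_l2())
        exact = solve_squared_l2(prob)
        grad = solve_power_p(prob)
        assert grad.objective == pytest.approx(exact.objective, rel=1e-8)

    def test_p4_two_free_matches_grid_oracle(self):
        rng = np.random.default_rng(12)
        coords = rng.uniform(0, 1, size=(5, 2))
        W = np.zeros((5, 5))
        W[3, 0] = W[3, 1] = 1.0
        W[4, 1] = W[4, 2] = 1.0
        W[3, 4] = 0.5
        fixed = np.array([True] * 3 + [False] * 2)
        prob = make_problem(W, fixed, coords, NormSpec.euclidean_power(4))
        sol = solve_power_p(prob)
        oracle = grid_search_objective(prob, -0.5, 1.5)
        assert sol.objective == pytest.approx(oracle, abs=1e-3)


# ---------------------------------------------------------------------------
# oracle equivalence across all solvers


@pytest.mark.parametrize("spec", ALL_SPECS, ids=lambda s: s.label)
@pytest.mark.parametrize("n_free", [1, 2])
def test_all_solvers_match_brute_force(spec, n_free):
    rng = np.random.default_rng(100 + n_free)
    n_anchor = 4
    n = n_anchor + n_free
    coords = rng.uniform(0, 1, size=(n, 2))
    W = rng.random((n, n)) * (rng.random((n, n)) < 0.7)
    W[:, :n_anchor][: n_anchor] *= 0.2  # keep anchor-anchor cost small
    np.fill_diagonal(W, 0.0)
    W[n_anchor:, :n_anchor] += 0.2  # guarantee anchoring
    fixed = np.array([True] * n_anchor + [False] * n_free)
    prob = make_problem(W, fixed, coords, spec)
    sol = solve(prob)
    oracle = grid_search_objective(prob, -0.5, 1.5)
    assert sol.objective == pytest.approx(oracle, abs=1e-3)
    assert sol.objective <= oracle + 1e-6


# ---------------------------------------------------------------------------
# equivariance and monotonicity


class TestEquivariance:
    @pytest.mark.parametrize(
        "spec", [NormSpec.l2(), NormSpec.squared_l2()], ids=lambda s: s.label
    )
    def test_rotation_equivariance(self, spec, single_free_two_anchors):
        W, fixed, coords = single_free_two_anchors
        theta = 0.7
        R = np.array(
            [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
        )
        sol = solve(make_problem(W, fixed, coords, spec))
        sol_rot = solve(make_problem(W, fixed, coords @ R.T, spec))
        np.testing.assert_allclose(sol_rot.layout[2], sol.layout[2] @ R.T,
                                   atol=1e-7)

    @pytest.mark.parametrize("spec", ALL_SPECS, ids=lambda s: s.label)
    def test_scaling_and_translation_equivariance(self, spec,
                                                  single_free_two_anchors):
        W, fixed, coords = single_free_two_anchors
        c, shift = 2.5, np.array([3.0, -1.0])
        sol = solve(make_problem(W, fixed, coords, spec))
        sol_t = solve(make_problem(W, fixed, c * coords + shift, spec))
        np.testing.assert_allclose(sol_t.layout[2], c * sol.layout[2] + shift,
                                   atol=1e-6)
        assert sol_t.objective == pytest.approx(
            c ** spec.homogeneity_degree * sol.objective, rel=1e-6
        )


@pytest.mark.parametrize("spec", ALL_SPECS, ids=lambda s: s.label)
def test_anchoring_monotonicity(worm_instance, spec):
    """Fixing additional nodes at their reference positions never lowers
    the optimal objective."""
    from wireopt import WeightScheme

    table, conn = worm_instance
    w = build_weights(conn, WeightScheme.unit_joint())
    prob = PlacementProblem(w, table.fixed_mask, table.coords, spec)
    base = solve(prob)
    extra = table.fixed_mask.copy()
    extra[np.flatnonzero(table.free_mask)[:10]] = True
    more = solve(PlacementProblem(w, extra, table.coords, spec))
    assert more.objective >= base.objective - 1e-8 * max(base.objective, 1.0)


# ---------------------------------------------------------------------------
# minimal-distance refinement


class TestMinDistance:
    def _two_coincident_free(self):
        # both free nodes pulled to the same midpoint of two anchors
        W = np.zeros((4, 4))
        W[2, 0] = W[2, 1] = 1.0
        W[3, 0] = W[3, 1] = 1.0
        coords = np.array([[0.0, 0.0], [2.0, 0.0], [0.5, 0.5], [1.5, -0.5]])
        fixed = np.array([True, True, False, False])
        return W, fixed, coords

    def test_forced_separation(self):
        W, fixed, coords = self._two_coincident_free()
        delta = 0.2
        prob = make_problem(W, fixed, coords, NormSpec.squared_l2(),
                            min_distance=delta)
        warm = solve_squared_l2(dataclasses.replace(prob, min_distance=None))
        # unconstrained optimum puts both free nodes at the same point
        assert np.linalg.norm(warm.layout[2] - warm.layout[3]) < 1e-9
        sol = solve_with_min_distance(prob, warm)
        d = np.linalg.norm(sol.layout[2] - sol.layout[3])
        assert d >= delta * (1 - 1e-9)
        assert sol.objective >= warm.objective
        # separating two quadratically-held points by delta costs O(delta^2)
        assert sol.objective - warm.objective < 4 * delta ** 2

    def test_inactive_constraint_returns_warm_unchanged(self):
        W, fixed, coords = self._two_coincident_free()
        coords[3] = [10.0, 0.0]
        W[3, 1] = 5.0  # node 3 settles at (5/3, 0); all gaps >> min_distance
        prob = make_problem(W, fixed, coords, NormSpec.squared_l2(),
                            min_distance=1e-6)
        warm = solve_squared_l2(dataclasses.replace(prob, min_distance=None))
        sol = solve_with_min_distance(prob, warm)
        assert sol is warm

    def test_near_coincident_pairs_cost_well_under_a_percent(self,
                                                             worm_instance):
        """A soma-scale exclusion radius barely changes the optimal TWL."""
        table, prob0 = _worm_problem(worm_instance, NormSpec.l2())
        delta = 2e-4  # soma-diameter scale, mm
        prob = dataclasses.replace(prob0, min_distance=delta)
        warm = solve_weber_l2(prob0)
        sol = solve_with_min_distance(prob, warm)
        from scipy.spatial.distance import pdist

        free_any = ~prob.fixed_mask
        n = prob.n
        iu, ju = np.triu_indices(n, k=1)
        keep = free_any[iu] | free_any[ju]
        d = np.linalg.norm(sol.layout[iu[keep]] - sol.layout[ju[keep]], axis=1)
        assert (d >= delta * (1 - 1e-9)).all()
        assert sol.objective >= warm.objective - 1e-9 * warm.objective
        increase_pct = 100 * (sol.objective - warm.objective) / warm.objective
        assert increase_pct < 0.1
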