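"""Problem assembly, boundary arithmetic, and dual-objective evaluation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from minset import (
    ConservationProblem,
    boundary_length,
    build_boundary,
    compute_targets,
    evaluate,
)
from tests.conftest import make_random_problem


class TestComputeTargets:
    def test_proportion_of_totals(self):
        amounts = np.array([[10.0], [20.0], [70.0]])
        assert compute_targets(amounts, 0.3) == pytest.approx([30.0])

    def test_full_proportion_requires_everything(self):
        amounts = np.ones((4, 2))
        t = compute_targets(amounts, 1.0)
        assert t == pytest.approx([4.0, 4.0])
        # only the all-selected vector reaches the totals
        prob = ConservationProblem(
            unit_ids=np.arange(4), cost=np.ones(4), amounts=amounts, targets=t
        )
        sol = evaluate(prob, np.ones(4))
        assert sol.feasible
        assert not evaluate(prob, np.array([1, 1, 1, 0])).feasible

    def test_proportion_grid_yields_nine_target_vectors(self):
        amounts = np.random.default_rng(0).uniform(0, 1, (5, 3))
        grid = [compute_targets(amounts, p) for p in np.arange(0.1, 0.91, 0.1)]
        assert len(grid) == 9

    @pytest.mark.parametrize("p", [0.0, -0.2, 1.1])
    def test_invalid_proportion_rejected(self, p):
        with pytest.raises(ValueError):
            compute_targets(np.ones((2, 1)), p)


def count_rook_edges(n_rows, n_cols):
    edges = 0
    for r in range(n_rows):
        for c in range(n_cols):
            if c + 1 < n_cols:
                edges += 1
            if r + 1 < n_rows:
                edges += 1
    return edges


class TestBuildBoundary:
    def test_single_cell(self):
        pairs, lengths, perim = build_boundary(1, 1)
        assert len(pairs) == 0
        assert perim == pytest.approx([4.0])

    def test_two_by_two(self):
        pairs, lengths, perim = build_boundary(2, 2)
        assert len(pairs) == 4
        assert np.all(lengths == 1.0)
        assert np.all(perim == 4.0)

    @pytest.mark.parametrize("rows,cols", [(3, 3), (2, 5), (4, 4), (1, 7)])
    def test_pair_count_matches_direct_enumeration(self, rows, cols):
        pairs, _, _ = build_boundary(rows, cols)
        assert len(pairs) == count_rook_edges(rows, cols)
        assert np.all(pairs[:, 0] < pairs[:, 1])

    def test_exterior_excluded_option(self):
        _, _, perim = build_boundary(2, 2, include_exterior=False)
        assert perim == pytest.approx([2.0, 2.0, 2.0, 2.0])


def direct_exposed_edges(n_rows, n_cols, x):
    """Count exposed unit-cell edges by brute force (exterior included)."""
    grid = np.asarray(x).reshape(n_rows, n_cols)
    total = 0
    for r in range(n_rows):
        for c in range(n_cols):
            if not grid[r, c]:
                continue
            for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                rr, cc = r + dr, c + dc
                if not (0 <= rr < n_rows and 0 <= cc < n_cols) or not grid[rr, cc]:
                    total += 1
    return float(total)


class TestBoundaryLength:
    def _grid_problem(self, rows, cols):
        return make_random_problem(seed=1, n_rows=rows, n_cols=cols)

    def test_single_selected_cell_has_full_perimeter(self):
        prob = self._grid_problem(3, 3)
        x = np.zeros(9)
        x[4] = 1
        assert boundary_length(prob, x) == pytest.approx(4.0)

    def test_two_by_two_block(self):
        prob = self._grid_problem(2, 2)
        assert boundary_length(prob, np.ones(4)) == pytest.approx(8.0)

    @pytest.mark.parametrize("rows,cols", [(2, 3), (4, 4), (3, 5)])
    def test_full_grid_perimeter_formula(self, rows, cols):
        prob = self._grid_problem(rows, cols)
        assert boundary_length(prob, np.ones(rows * cols)) == pytest.approx(
            2.0 * (rows + cols)
        )

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(0, 2**9 - 1))
    def test_quadratic_form_equals_direct_edge_count(self, mask):
        prob = self._grid_problem(3, 3)
        x = np.array([(mask >> i) & 1 for i in range(9)], dtype=float)
        assert boundary_length(prob, x) == pytest.approx(
            direct_exposed_edges(3, 3, x), rel=1e-9
        )


def sa_objective_oracle(problem, x, spf, penalties):
    """Independent scalar-loop evaluation of the penalized objective."""
    total = 0.0
    for i in range(problem.n_units):
        total += problem.cost[i] * x[i]
    total += problem.blm * direct_exposed_edges(3, 3, x)
    for j in range(problem.n_features):
        held = sum(problem.amounts[i, j] * x[i] for i in range(problem.n_units))
        t = problem.targets[j]
        short = max(0.0, t - held)
        if t > 0:
            total += spf * penalties[j] * short / t
    return total


class TestEvaluate:
    def test_feasible_selection_has_no_penalty(self, small_problem):
        x = np.ones(small_problem.n_units)
        sol = evaluate(small_problem, x, spf=25.0, feature_penalties=np.ones(2) * 50)
        assert sol.feasible
        assert sol.sa_objective == pytest.approx(
            sol.total_cost + small_problem.blm * sol.boundary_length
        )

    def test_empty_selection_pays_full_shortfall_ratio(self):
        amounts = np.array([[10.0], [20.0], [70.0]])
        prob = ConservationProblem(
            unit_ids=np.arange(3), cost=np.ones(3), amounts=amounts,
            targets=np.array([30.0]),
        )
        sol = evaluate(prob, np.zeros(3), spf=5.0, feature_penalties=np.array([50.0]))
        assert sol.sa_objective == pytest.approx(250.0)
        assert sol.n_targets_met == 0

    def test_zero_target_feature_always_met(self):
        amounts = np.ones((2, 2))
        prob = ConservationProblem(
            unit_ids=np.arange(2), cost=np.ones(2), amounts=amounts,
            targets=np.array([0.0, 1.0]),
        )
        sol = evaluate(prob, np.zeros(2), spf=5.0, feature_penalties=np.array([9.0, 9.0]))
        assert sol.n_targets_met == 1
        assert sol.shortfalls[0] == 0.0

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_scalar_loop_oracle(self, seed):
        prob = make_random_problem(seed=seed, n_rows=3, n_cols=3, blm=0.7)
        rng = np.random.default_rng(seed + 100)
        x = (rng.random(9) < 0.5).astype(float)
        penalties = rng.uniform(1, 20, prob.n_features)
        sol = evaluate(prob, x, spf=5.0, feature_penalties=penalties)
        assert sol.sa_objective == pytest.approx(
            sa_objective_oracle(prob, x, 5.0, penalties), rel=1e-9
        )

    def test_length_mismatch_rejected(self, small_problem):
        with pytest.raises(ValueError, match="shape"):
            evaluate(small_problem, np.zeros(4))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2**9 - 1), st.integers(0, 10_000))
    def test_penalized_objective_dominates_plain_objective(self, mask, seed):
        prob = make_random_problem(seed=seed % 50, blm=0.3)
        x = np.array([(mask >> i) & 1 for i in range(9)], dtype=float)
        pen = np.random.default_rng(seed).uniform(0.5, 10, prob.n_features)
        sol = evaluate(prob, x, spf=7.0, feature_penalties=pen)
        assert sol.sa_objective >= sol.ilp_objective - 1e-12
        assert (sol.sa_objective == pytest.approx(sol.ilp_objective)) == sol.feasible

    def test_blm_zero_makes_objectives_equal_cost(self, small_problem):
        x = np.ones(small_problem.n_units)
        sol = evaluate(small_problem, x)
        assert sol.ilp_objective == pytest.approx(sol.total_cost)
        assert sol.sa_objective is None


class TestProblemInvariants:
    def test_unreachable_targets_rejected_at_construction(self):
        with pytest.raises(ValueError, match="infeasible"):
            ConservationProblem(
                unit_ids=np.arange(2), cost=np.ones(2),
                amounts=np.ones((2, 1)), targets=np.array([3.0]),
            )

    def test_nonpositive_cost_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            ConservationProblem(
                unit_ids=np.arange(2), cost=np.array([1.0, 0.0]),
                amounts=np.ones((2, 1)), targets=np.array([1.0]),
            )

    def test_targets_monotonically_harder(self):
        prob_lo = make_random_problem(seed=3, proportion=0.3)
        prob_hi = make_random_problem(seed=3, proportion=0.7)
        rng = np.random.default_rng(0)
        for _ in range(20):
            x = (rng.random(9) < 0.5).astype(float)
            met_lo = evaluate(prob_lo, x).n_targets_met
            met_hi = evaluate(prob_hi, x).n_targets_met
            assert met_hi <= met_lo
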