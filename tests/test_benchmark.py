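"""Scenario grids, sweep execution, and summary metric arithmetic."""

import numpy as np
import pandas as pd
import pytest

from minset import (
    SAParams,
    ScenarioGrid,
    build_scenario_grid,
    landscape_problem_factory,
    run_benchmark,
    summarize_blm,
    summarize_savings,
)

STUDY_TARGETS = tuple(np.round(np.arange(0.1, 0.91, 0.1), 2))


class TestGridArithmetic:
    def test_exact_route_grid_is_135(self):
        grid = ScenarioGrid(
            target_proportions=STUDY_TARGETS,
            feature_counts=(10, 26, 41, 56, 72),
            extents=(9282, 37128, 148510),
            mode="ilp",
        )
        assert len(build_scenario_grid(grid)) == 135

    def test_annealing_grid_is_2700(self):
        grid = ScenarioGrid(
            target_proportions=STUDY_TARGETS,
            feature_counts=(10, 26, 41, 56, 72),
            extents=(9282, 37128, 148510),
            sa_iteration_counts=(10**4, 10**5, 10**6, 10**7, 10**8),
            sa_spf_values=(1, 5, 25, 125),
            mode="sa",
        )
        assert len(build_scenario_grid(grid)) == 2700

    def test_boundary_sweep_grid_is_45(self):
        grid = ScenarioGrid(
            target_proportions=STUDY_TARGETS,
            blm_values=(0.1, 1, 10, 100, 1000),
            mode="blm_sweep",
        )
        assert len(build_scenario_grid(grid)) == 45

    def test_targets_are_the_outermost_axis(self):
        grid = ScenarioGrid(
            target_proportions=(0.1, 0.2),
            feature_counts=(2, 3),
            extents=(4,),
            mode="ilp",
        )
        scenarios = build_scenario_grid(grid)
        assert [s.target_proportion for s in scenarios] == [0.1, 0.1, 0.2, 0.2]
        assert [s.n_features for s in scenarios] == [2, 3, 2, 3]
        assert [s.index for s in scenarios] == [0, 1, 2, 3]

    def test_empty_axis_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            build_scenario_grid(ScenarioGrid(target_proportions=(), mode="ilp"))
        with pytest.raises(ValueError, match="empty"):
            build_scenario_grid(
                ScenarioGrid(target_proportions=(0.3,), feature_counts=(2,),
                             extents=(4,), mode="sa")
            )
        with pytest.raises(ValueError, match="mode"):
            build_scenario_grid(ScenarioGrid(target_proportions=(0.3,), mode="exact"))


@pytest.fixture(scope="module")
def tiny_sweep():
    grid = ScenarioGrid(
        target_proportions=(0.3,),
        blm_values=(0.0, 1.0),
        mode="blm_sweep",
    )
    factory = landscape_problem_factory(blm_extent=16, blm_n_features=2)
    params = SAParams(spf=25.0, n_iterations=3000, n_restarts=3)
    return run_benchmark(build_scenario_grid(grid), factory, params, master_seed=5)


class TestRunBenchmark:
    def test_blm_scenarios_yield_two_records_each(self, tiny_sweep):
        assert len(tiny_sweep) == 4
        assert set(tiny_sweep.solver) == {"ilp", "sa"}
        assert tiny_sweep.error.isna().all()

    def test_deterministic_rerun(self):
        grid = ScenarioGrid(target_proportions=(0.4,), feature_counts=(2,),
                            extents=(16,), mode="ilp")
        factory = landscape_problem_factory()
        a = run_benchmark(build_scenario_grid(grid), factory, master_seed=1)
        b = run_benchmark(build_scenario_grid(grid), factory, master_seed=1)
        cols = [c for c in a.columns if c != "runtime"]
        pd.testing.assert_frame_equal(a[cols], b[cols])

    def test_failures_are_recorded_not_fatal(self):
        def bad_factory(scenario):
            raise RuntimeError("boom")

        grid = ScenarioGrid(target_proportions=(0.4,), feature_counts=(2,),
                            extents=(16,), mode="ilp")
        out = run_benchmark(build_scenario_grid(grid), bad_factory, master_seed=0)
        assert len(out) == 1
        assert out.error.iloc[0] == "boom"
        assert out.solver.iloc[0] == "none"

    def test_incremental_results_file(self, tmp_path):
        grid = ScenarioGrid(target_proportions=(0.4,), feature_counts=(2,),
                            extents=(16,), mode="ilp")
        path = tmp_path / "results.csv"
        out = run_benchmark(
            build_scenario_grid(grid), landscape_problem_factory(),
            master_seed=0, results_path=path,
        )
        on_disk = pd.read_csv(path)
        assert len(on_disk) == len(out) == 1


class TestSummarizeSavings:
    def _fixture(self):
        rows = []
        # known costs: ILP 90 everywhere; SA varies
        for t, sa_cost, iters, spf in [
            (0.1, 100.0, 10_000, 5),
            (0.2, 90.0, 10_000, 25),
            (0.3, 120.0, 10_000, 5),
            (0.4, 95.0, 1_000, 5),   # excluded by iteration filter
            (0.5, 180.0, 10_000, 1),  # excluded by spf filter
        ]:
            rows.append(dict(mode="sa", target_proportion=t, n_features=2, n_units=16,
                             sa_iterations=iters, sa_spf=spf, blm=None, solver="sa",
                             total_cost=sa_cost, feasible=True, error=None))
            rows.append(dict(mode="ilp", target_proportion=t, n_features=2, n_units=16,
                             sa_iterations=None, sa_spf=None, blm=None, solver="ilp",
                             total_cost=90.0, feasible=True, error=None))
        return pd.DataFrame(rows)

    def test_definitional_arithmetic(self):
        table, _ = summarize_savings(self._fixture())
        row = table[table.target_proportion == 0.1].iloc[0]
        assert row.savings_vs_sa == pytest.approx(10.0)
        assert row.excess_vs_ilp == pytest.approx(100.0 / 9.0)
        row = table[table.target_proportion == 0.2].iloc[0]
        assert row.savings_vs_sa == pytest.approx(0.0)
        assert row.excess_vs_ilp == pytest.approx(0.0)

    def test_calibrated_aggregates_match_hand_computation(self):
        _, agg = summarize_savings(
            self._fixture(), min_iterations=1_000, spf_values=(5, 25)
        )
        # calibrated subset: SA costs 100, 90, 120 vs ILP 90
        assert agg["n_calibrated"] == 3
        assert agg["savings_min"] == pytest.approx(0.0)
        assert agg["savings_median"] == pytest.approx(10.0)
        assert agg["savings_max"] == pytest.approx(25.0)

    def test_unpaired_records_are_dropped(self):
        df = self._fixture()
        df = df[~((df.solver == "ilp") & (df.target_proportion == 0.1))]
        table, agg = summarize_savings(df)
        assert agg["n_pairs"] == 4
        assert 0.1 not in set(table.target_proportion)


class TestSummarizeBlm:
    def test_deviation_arithmetic(self):
        df = pd.DataFrame([
            dict(target_proportion=0.1, blm=1.0, solver="ilp", ilp_objective=100.0,
                 total_cost=80.0, boundary_length=20.0, feasible=True, error=None),
            dict(target_proportion=0.1, blm=1.0, solver="sa", ilp_objective=120.0,
                 total_cost=90.0, boundary_length=30.0, feasible=True, error=None),
            dict(target_proportion=0.2, blm=1.0, solver="ilp", ilp_objective=50.0,
                 total_cost=40.0, boundary_length=10.0, feasible=True, error=None),
            dict(target_proportion=0.2, blm=1.0, solver="sa", ilp_objective=50.0,
                 total_cost=40.0, boundary_length=10.0, feasible=True, error=None),
        ])
        out = summarize_blm(df)
        dev = {(r.target_proportion, r.solver): r.deviation_pct for r in out.itertuples()}
        assert dev[(0.1, "ilp")] == pytest.approx(0.0)
        assert dev[(0.1, "sa")] == pytest.approx(20.0)
        assert dev[(0.2, "ilp")] == pytest.approx(0.0)
        assert dev[(0.2, "sa")] == pytest.approx(0.0)

    def test_exact_solver_attains_zero_deviation_in_live_sweep(self, tiny_sweep):
        out = summarize_blm(tiny_sweep)
        ilp_rows = out[out.solver == "ilp"]
        assert np.allclose(ilp_rows.deviation_pct, 0.0, atol=1e-9)
        feas = out[out.feasible == True]  # noqa: E712
        assert (feas.deviation_pct >= -1e-9).all()
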