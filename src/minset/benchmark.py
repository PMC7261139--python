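"""Scenario-grid benchmarks comparing the exact and annealing solvers.

The experimental design is a cartesian grid over problem axes (target
proportion, number of features, problem extent) and, for the annealer,
calibration axes (iteration count, species penalty factor). A separate
sweep varies the boundary penalty weight (BLM) at fixed extent to probe
compactness trade-offs. For each scenario the exact solver provides the
certified optimum; the annealer reports its best-of-restarts solution.
Summaries compute the cost saved by the exact route relative to the
annealer and each solver's deviation from the best objective in the
boundary-penalty sweep.

All runs derive their randomness from one master seed, so a completed
sweep is exactly reproducible (the runtime column aside).
"""

from __future__ import annotations

import itertools
import logging
import time
from dataclasses import dataclass, replace
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .ilp import build_milp, solve_milp
from .problem import ConservationProblem
from .sa import SAParams, run_restarts

__all__ = [
    "ScenarioGrid",
    "Scenario",
    "build_scenario_grid",
    "run_benchmark",
    "summarize_savings",
    "summarize_blm",
    "landscape_problem_factory",
]

logger = logging.getLogger("minset.benchmark")

RESULT_COLUMNS = [
    "mode",
    "scenario_index",
    "target_proportion",
    "n_features",
    "n_units",
    "sa_iterations",
    "sa_spf",
    "blm",
    "solver",
    "total_cost",
    "ilp_objective",
    "sa_objective",
    "boundary_length",
    "n_targets_met",
    "feasible",
    "optimal",
    "mip_gap",
    "dual_bound",
    "seed",
    "runtime",
    "error",
]


@dataclass(frozen=True)
class Scenario:
    """One point of the experiment grid (unused axes are None)."""

    index: int
    mode: str
    target_proportion: float
    n_features: int | None = None
    n_units: int | None = None
    sa_iterations: int | None = None
    sa_spf: float | None = None
    blm: float | None = None


@dataclass(frozen=True)
class ScenarioGrid:
    """Axes of the experiment design.

    mode 'ilp' crosses targets x feature counts x extents; mode 'sa'
    additionally crosses iteration counts x penalty factors; mode
    'blm_sweep' crosses targets x boundary-penalty weights at a fixed
    extent/feature count.
    """

    target_proportions: Sequence[float]
    feature_counts: Sequence[int] = ()
    extents: Sequence[int] = ()
    sa_iteration_counts: Sequence[int] = ()
    sa_spf_values: Sequence[float] = ()
    blm_values: Sequence[float] = ()
    mode: str = "ilp"


def build_scenario_grid(grid: ScenarioGrid) -> list[Scenario]:
    """Expand a grid spec into the full ordered scenario list.

    Lexicographic cartesian product with targets outermost; the counts
    obey |targets|*|features|*|extents| (ilp), additionally *|iterations|
    *|spf| (sa), and |targets|*|blm| (blm_sweep).
    """
    if grid.mode not in ("ilp", "sa", "blm_sweep"):
        raise ValueError(f"unknown grid mode {grid.mode!r}")

    def need(name: str, axis: Sequence) -> Sequence:
        if len(axis) == 0:
            raise ValueError(f"grid axis {name!r} is empty for mode {grid.mode!r}")
        return axis

    targets = need("target_proportions", grid.target_proportions)
    scenarios: list[Scenario] = []
    if grid.mode == "ilp":
        prod = itertools.product(
            targets, need("feature_counts", grid.feature_counts), need("extents", grid.extents)
        )
        for idx, (t, m, n) in enumerate(prod):
            scenarios.append(Scenario(idx, "ilp", t, n_features=m, n_units=n))
    elif grid.mode == "sa":
        prod = itertools.product(
            targets,
            need("feature_counts", grid.feature_counts),
            need("extents", grid.extents),
            need("sa_iteration_counts", grid.sa_iteration_counts),
            need("sa_spf_values", grid.sa_spf_values),
        )
        for idx, (t, m, n, it, spf) in enumerate(prod):
            scenarios.append(
                Scenario(idx, "sa", t, n_features=m, n_units=n, sa_iterations=it, sa_spf=spf)
            )
    else:
        prod = itertools.product(targets, need("blm_values", grid.blm_values))
        for idx, (t, b) in enumerate(prod):
            scenarios.append(Scenario(idx, "blm_sweep", t, blm=b))
    return scenarios


def landscape_problem_factory(
    fine_factor: int = 2,
    correlation_range: float = 4.0,
    prevalence: float = 0.25,
    steepness: float = 2.0,
    landscape_seed: int = 20_200_527,
    blm_extent: int = 36,
    blm_n_features: int = 6,
) -> Callable[[Scenario], ConservationProblem]:
    """Factory building problems from cached synthetic landscapes.

    For each extent (a square planning-unit count) a fine raster of
    ``fine_factor``-times resolution is generated once, then aggregated
    (cost summed, occupancy averaged) and trimmed to the first k features
    in manifest order for the scenario's feature count. BLM-sweep
    scenarios use a fixed extent and feature count with the scenario's
    boundary weight.
    """
    from .landscape import aggregate_landscape, generate_landscape
    from .problem import problem_from_landscape

    cache: dict[tuple[int, int], object] = {}

    def get_landscape(n_units: int, n_features: int):
        key = (n_units, n_features)
        if key not in cache:
            side = int(round(np.sqrt(n_units)))
            if side * side != n_units:
                raise ValueError(f"extent {n_units} is not a square unit count")
            fine = generate_landscape(
                n_features=n_features,
                n_rows=side * fine_factor,
                n_cols=side * fine_factor,
                correlation_range=correlation_range,
                prevalence=prevalence,
                steepness=steepness,
                seed=landscape_seed,
            )
            cache[key] = aggregate_landscape(fine, fine_factor)
        return cache[key]

    def factory(scenario: Scenario) -> ConservationProblem:
        if scenario.mode == "blm_sweep":
            n_units, n_features = blm_extent, blm_n_features
            blm = float(scenario.blm)
        else:
            n_units, n_features = scenario.n_units, scenario.n_features
            blm = 0.0
        ls = get_landscape(n_units, n_features)
        return problem_from_landscape(ls, scenario.target_proportion, blm=blm)

    return factory


def _record(scenario: Scenario, solver: str, seed: int, runtime: float, sol=None, error=None):
    rec = {
        "mode": scenario.mode,
        "scenario_index": scenario.index,
        "target_proportion": scenario.target_proportion,
        "n_features": scenario.n_features,
        "n_units": scenario.n_units,
        "sa_iterations": scenario.sa_iterations,
        "sa_spf": scenario.sa_spf,
        "blm": scenario.blm,
        "solver": solver,
        "seed": seed,
        "runtime": runtime,
        "error": error,
    }
    if sol is not None:
        rec.update(
            total_cost=sol.total_cost,
            ilp_objective=sol.ilp_objective,
            sa_objective=sol.sa_objective,
            boundary_length=sol.boundary_length,
            n_targets_met=sol.n_targets_met,
            feasible=sol.feasible,
            optimal=bool(sol.provenance.get("optimal", False)),
            mip_gap=sol.provenance.get("mip_gap", np.nan),
            dual_bound=sol.provenance.get("dual_bound", np.nan),
        )
    return rec


def run_benchmark(
    scenarios: Iterable[Scenario],
    problem_factory: Callable[[Scenario], ConservationProblem],
    sa_params: SAParams | None = None,
    backend: str = "highs",
    master_seed: int = 0,
    gap_tolerance: float = 0.0,
    time_limit: float | None = None,
    results_path=None,
) -> pd.DataFrame:
    """Run every scenario and return a tidy result table.

    'ilp' scenarios run the exact solver; 'sa' scenarios run
    best-of-restarts annealing (iteration count and penalty factor taken
    from the scenario); 'blm_sweep' scenarios run both solvers on the
    same problem. Per-scenario seeds derive from ``(master_seed, index)``.
    Individual scenario failures are recorded in the ``error`` column
    rather than aborting the sweep; rows are appended to ``results_path``
    (CSV) incrementally when given, so long sweeps are resumable by hand.
    """
    if sa_params is None:
        sa_params = SAParams()
    rows: list[dict] = []
    n_failed = 0
    wrote_header = False

    for scenario in scenarios:
        seed = int(np.random.SeedSequence([int(master_seed), scenario.index]).generate_state(1)[0])
        try:
            problem = problem_factory(scenario)
            new_rows = []
            if scenario.mode in ("ilp", "blm_sweep"):
                t0 = time.perf_counter()
                sol = solve_milp(
                    build_milp(problem),
                    backend=backend,
                    gap_tolerance=gap_tolerance,
                    time_limit=time_limit,
                )
                new_rows.append(_record(scenario, "ilp", seed, time.perf_counter() - t0, sol))
            if scenario.mode in ("sa", "blm_sweep"):
                params = replace(
                    sa_params,
                    seed=seed,
                    n_iterations=scenario.sa_iterations or sa_params.n_iterations,
                    spf=scenario.sa_spf if scenario.sa_spf is not None else sa_params.spf,
                )
                t0 = time.perf_counter()
                best, _ = run_restarts(problem, params)
                new_rows.append(_record(scenario, "sa", seed, time.perf_counter() - t0, best))
        except Exception as exc:  # failures are data, not fatalities
            logger.warning("scenario %d failed: %s", scenario.index, exc)
            n_failed += 1
            new_rows = [_record(scenario, "none", seed, 0.0, error=str(exc))]
        for rec in new_rows:
            logger.info(
                "scenario %d [%s/%s]: cost=%s feasible=%s",
                scenario.index,
                scenario.mode,
                rec["solver"],
                rec.get("total_cost"),
                rec.get("feasible"),
            )
        rows.extend(new_rows)
        if results_path is not None:
            pd.DataFrame(new_rows).reindex(columns=RESULT_COLUMNS).to_csv(
                results_path, mode="a", header=not wrote_header, index=False
            )
            wrote_header = True

    if n_failed:
        logger.warning("%d scenario(s) failed", n_failed)
    return pd.DataFrame(rows).reindex(columns=RESULT_COLUMNS)


def _pair_key(df: pd.DataFrame) -> pd.DataFrame:
    key_cols = ["target_proportion", "n_features", "n_units", "blm"]
    out = df.copy()
    for col in key_cols:
        if col not in out:
            out[col] = np.nan
    return out


def summarize_savings(
    results: pd.DataFrame,
    ilp_results: pd.DataFrame | None = None,
    min_iterations: int = 0,
    spf_values: Sequence[float] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Cost savings of the exact solver over the annealer, per scenario.

    Pairs each annealing record with the exact record for the same
    (target, features, extent) cell and computes

        savings_vs_sa  = (SA_cost - ILP_cost) / SA_cost * 100
        excess_vs_ilp  = (SA_cost - ILP_cost) / ILP_cost * 100

    Aggregates (min/median/max of savings) are reported over the
    "calibrated" subset: annealing records with more than
    ``min_iterations`` iterations and penalty factor in ``spf_values``
    (no filter when left at the permissive defaults). Cells without a
    matching exact record are dropped with a warning.
    """
    df = results if ilp_results is None else pd.concat([results, ilp_results])
    df = _pair_key(df)
    sa = df[(df.solver == "sa") & df.error.isna()].copy()
    ilp = df[(df.solver == "ilp") & df.error.isna()].copy()
    key = ["target_proportion", "n_features", "n_units"]
    ilp_costs = ilp.groupby(key, dropna=False)["total_cost"].min().rename("ilp_cost")
    merged = sa.merge(ilp_costs, left_on=key, right_index=True, how="left")
    missing = merged.ilp_cost.isna()
    if missing.any():
        logger.warning("%d annealing record(s) lack a matching exact record", missing.sum())
        merged = merged[~missing]
    merged["savings_vs_sa"] = (
        (merged.total_cost - merged.ilp_cost) / merged.total_cost * 100.0
    )
    merged["excess_vs_ilp"] = (
        (merged.total_cost - merged.ilp_cost) / merged.ilp_cost * 100.0
    )

    calibrated = merged
    if min_iterations:
        calibrated = calibrated[calibrated.sa_iterations > min_iterations]
    if spf_values is not None:
        calibrated = calibrated[calibrated.sa_spf.isin(list(spf_values))]
    feasible = calibrated[calibrated.feasible == True]  # noqa: E712
    agg = {
        "n_pairs": int(len(merged)),
        "n_calibrated": int(len(calibrated)),
        "n_calibrated_feasible": int(len(feasible)),
        "savings_min": float(feasible.savings_vs_sa.min()) if len(feasible) else np.nan,
        "savings_median": float(feasible.savings_vs_sa.median()) if len(feasible) else np.nan,
        "savings_max": float(feasible.savings_vs_sa.max()) if len(feasible) else np.nan,
    }
    return merged, agg


def summarize_blm(results: pd.DataFrame) -> pd.DataFrame:
    """Per (target, blm) cell, each solver's % deviation from the best objective.

    Deviation is relative to the minimum ``ilp_objective`` among *feasible*
    records in the cell — an infeasible selection (e.g. the annealer
    collapsing to the empty set under a crushing boundary weight) has an
    artificially low raw objective and cannot anchor the comparison. The
    solver attaining the feasible minimum has deviation 0; for an exact
    solve at gap 0 that is always the exact record. Infeasible records
    keep their (possibly negative) deviation and their feasibility flag.
    """
    df = _pair_key(results)
    df = df[df.error.isna() & (df.solver != "none")].copy()
    key = ["target_proportion", "blm"]
    best = (
        df[df.feasible == True]  # noqa: E712
        .groupby(key, dropna=False)["ilp_objective"]
        .min()
        .rename("best_objective")
    )
    out = df.merge(best, left_on=key, right_index=True, how="left")
    out["deviation_pct"] = (
        (out.ilp_objective - out.best_objective) / out.best_objective * 100.0
    )
    return out[key + ["solver", "ilp_objective", "best_objective", "deviation_pct",
                      "total_cost", "boundary_length", "feasible"]]
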