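"""Desk-scale study definitions: the experiments the package reports.

The full-scale experimental design crosses nine target levels with five
feature counts and three extents (135 exact-solver scenarios; 2,700
annealing scenarios once five iteration counts and four penalty factors
are added) and a 45-cell boundary-penalty sweep. Those extents (up to
~150,000 planning units) and iteration counts (up to 1e8) are not
desk-reproducible, so the package fixes a scaled-down set of study
conditions, declared here once and used by the analysis scripts, the
acceptance checks and the reproduction script alike:

* extents 100 / 400 / 2,500 units (10x10, 20x20, 50x50 grids, aggregated
  2:1 from a finer synthetic raster),
* feature counts 10 / 26 / 72 (first-k in manifest order),
* targets 10%-90% in 10% steps,
* annealing iteration axis 1e3 / 1e4 / 1e5, penalty factors 1/5/25/125,
  best of 10 restarts,
* boundary sweep on a 6x6-unit landscape with 6 features and boundary
  weights 0.1 / 1 / 10 / 100 / 1,000, certified at gap 0,
* the cost sweep's exact solves use a 1% certification gap with the
  solver's proven dual bound recorded, because closing the last fraction
  of a percent on these dense fractional-coverage instances is slow out
  of all proportion to its effect on the comparison; every dominance
  statement is checked against the certified dual bound, which is valid
  at any gap.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .benchmark import (
    ScenarioGrid,
    build_scenario_grid,
    landscape_problem_factory,
    run_benchmark,
    summarize_blm,
    summarize_savings,
)
from .ilp import brute_force, build_milp, solve_milp
from .problem import ConservationProblem, build_boundary, compute_targets
from .sa import SAParams, run_restarts

__all__ = [
    "DESK_TARGETS",
    "DESK_FEATURE_COUNTS",
    "DESK_EXTENTS",
    "DESK_SA_ITERATIONS",
    "SPF_GRID",
    "BLM_VALUES",
    "FULL_FEATURE_COUNTS",
    "FULL_EXTENTS",
    "FULL_SA_ITERATIONS",
    "random_grid_problem",
    "oracle_equivalence_study",
    "cost_sweep_study",
    "blm_sweep_study",
    "calibration_study",
]

DESK_TARGETS = tuple(np.round(np.arange(0.1, 0.91, 0.1), 2))
DESK_FEATURE_COUNTS = (10, 26, 72)
DESK_EXTENTS = (100, 400, 2500)
DESK_SA_ITERATIONS = (1_000, 10_000, 100_000)
SPF_GRID = (1.0, 5.0, 25.0, 125.0)
BLM_VALUES = (0.1, 1.0, 10.0, 100.0, 1000.0)

# full-scale design axes (for scenario-count arithmetic only)
FULL_FEATURE_COUNTS = (10, 26, 41, 56, 72)
FULL_EXTENTS = (9_282, 37_128, 148_510)
FULL_SA_ITERATIONS = (10**4, 10**5, 10**6, 10**7, 10**8)

# sweep protocol constants, fixed ahead of any measurement
SWEEP_SA_ITERATIONS = 10_000
SWEEP_SA_SPF = 25.0
SWEEP_SA_RESTARTS = 10
SWEEP_ILP_GAP = 0.01
SWEEP_ILP_TIME_LIMIT = 60.0
BLM_EXTENT = 36
BLM_N_FEATURES = 6
CALIBRATION_EXTENT = 100
CALIBRATION_N_FEATURES = 6
CALIBRATION_TARGET = 0.5
CALIBRATION_N_INSTANCES = 20


def random_grid_problem(
    seed: int,
    n_rows: int = 3,
    n_cols: int = 3,
    n_features: int = 2,
    proportion: float = 0.4,
    blm: float = 0.0,
) -> ConservationProblem:
    """Small random grid instance: lognormal costs, uniform amounts."""
    rng = np.random.default_rng(seed)
    n = n_rows * n_cols
    cost = np.exp(rng.normal(0, 1, n))
    amounts = rng.uniform(0.0, 1.0, (n, n_features))
    pairs, lengths, perim = build_boundary(n_rows, n_cols)
    return ConservationProblem(
        unit_ids=np.arange(1, n + 1),
        cost=cost,
        amounts=amounts,
        targets=compute_targets(amounts, proportion),
        boundary_pairs=pairs,
        boundary_lengths=lengths,
        total_perimeter=perim,
        blm=blm,
        target_proportion=proportion,
    )


def oracle_equivalence_study(seed: int = 0, n_instances: int = 210) -> dict:
    """Exact-solver cross-validation against exhaustive enumeration.

    Random instances of at most 16 units (3x3, 3x4 and 4x4 grids in
    rotation), boundary weights cycling through 0, 1 and 10, target
    proportions spread over [0.2, 0.8]. Returns the agreement count and
    the largest relative objective discrepancy observed.
    """
    geoms = [(3, 3), (3, 4), (4, 4)]
    blms = [0.0, 1.0, 10.0]
    n_agree = 0
    worst = 0.0
    for k in range(n_instances):
        rows, cols = geoms[k % 3]
        prob = random_grid_problem(
            seed=seed * 1_000_003 + k,
            n_rows=rows,
            n_cols=cols,
            n_features=2,
            proportion=0.2 + 0.6 * ((k // 3) % 7) / 6.0,
            blm=blms[(k // 9) % 3],
        )
        exact = solve_milp(build_milp(prob), gap_tolerance=0.0)
        oracle = brute_force(prob)
        rel = abs(exact.ilp_objective - oracle.ilp_objective) / max(
            abs(oracle.ilp_objective), 1e-12
        )
        worst = max(worst, rel)
        if rel <= 1e-6:
            n_agree += 1
    return {"n_instances": n_instances, "n_agree": n_agree, "max_rel_diff": worst}


def _desk_factory():
    return landscape_problem_factory(
        blm_extent=BLM_EXTENT, blm_n_features=BLM_N_FEATURES
    )


def cost_sweep_study(
    master_seed: int = 0,
    targets=DESK_TARGETS,
    feature_counts=DESK_FEATURE_COUNTS,
    extents=DESK_EXTENTS,
    sa_iterations: int = SWEEP_SA_ITERATIONS,
    sa_spf: float = SWEEP_SA_SPF,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Exact-vs-annealing cost sweep over the desk axes.

    Runs the exact solver (1% certification gap, dual bound recorded) and
    best-of-10 annealing at the calibrated setting (1e4 iterations,
    penalty factor 25) on every (target, feature count, extent) cell,
    then pairs the records into per-cell cost savings.
    Returns (raw results, per-cell savings table, aggregates).
    """
    factory = _desk_factory()
    ilp_grid = ScenarioGrid(
        target_proportions=targets,
        feature_counts=feature_counts,
        extents=extents,
        mode="ilp",
    )
    sa_grid = ScenarioGrid(
        target_proportions=targets,
        feature_counts=feature_counts,
        extents=extents,
        sa_iteration_counts=(sa_iterations,),
        sa_spf_values=(sa_spf,),
        mode="sa",
    )
    sa_params = SAParams(n_restarts=SWEEP_SA_RESTARTS)
    ilp_res = run_benchmark(
        build_scenario_grid(ilp_grid),
        factory,
        master_seed=master_seed,
        gap_tolerance=SWEEP_ILP_GAP,
        time_limit=SWEEP_ILP_TIME_LIMIT,
    )
    sa_res = run_benchmark(
        build_scenario_grid(sa_grid),
        factory,
        sa_params=sa_params,
        master_seed=master_seed + 1,
    )
    results = pd.concat([ilp_res, sa_res], ignore_index=True)
    savings, agg = summarize_savings(results)
    return results, savings, agg


def blm_sweep_study(master_seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Boundary-penalty sweep: both solvers on every (target, blm) cell.

    The exact solves are certified at gap 0 so the deviation-from-best
    structure and the boundary-vs-weight trade-off reflect true optima.
    Returns (raw results, deviation table).
    """
    grid = ScenarioGrid(
        target_proportions=DESK_TARGETS, blm_values=BLM_VALUES, mode="blm_sweep"
    )
    sa_params = SAParams(
        spf=SWEEP_SA_SPF,
        n_iterations=SWEEP_SA_ITERATIONS,
        n_restarts=SWEEP_SA_RESTARTS,
    )
    results = run_benchmark(
        build_scenario_grid(grid),
        _desk_factory(),
        sa_params=sa_params,
        master_seed=master_seed,
        gap_tolerance=0.0,
        time_limit=120.0,
    )
    return results, summarize_blm(results)


def _calibration_problem(master_seed: int, instance: int) -> ConservationProblem:
    from .landscape import aggregate_landscape, generate_landscape
    from .problem import problem_from_landscape

    fine = generate_landscape(
        n_features=CALIBRATION_N_FEATURES,
        n_rows=20,
        n_cols=20,
        correlation_range=4.0,
        prevalence=0.25,
        steepness=2.0,
        seed=int(
            np.random.SeedSequence([master_seed, 0xCA11B, instance]).generate_state(1)[0]
        ),
    )
    return problem_from_landscape(aggregate_landscape(fine, 2), CALIBRATION_TARGET)


def calibration_study(
    master_seed: int = 0, n_instances: int = CALIBRATION_N_INSTANCES
) -> dict:
    """Annealer calibration behaviour on 100-unit instances.

    For each of ``n_instances`` independent synthetic landscapes:

    * the certified optimum (gap 0);
    * best-of-10 annealing at penalty factor 25 for iteration counts
      1e3 / 1e4 / 1e5, recording the relative cost gap of the best
      feasible run over the optimum;
    * a penalty-factor-0 run (the empty selection is then optimal);
    * best-of-10 at penalty factor 125 and 1e4 iterations, recording
      whether every target is met.
    """
    gaps: dict[int, list[float]] = {it: [] for it in DESK_SA_ITERATIONS}
    n_spf0_empty = 0
    n_spf125_met = 0
    for inst in range(n_instances):
        prob = _calibration_problem(master_seed, inst)
        opt = solve_milp(build_milp(prob), gap_tolerance=0.0, time_limit=120.0)
        run_seed = int(
            np.random.SeedSequence([master_seed, 0x5EED, inst]).generate_state(1)[0]
        )
        for it in DESK_SA_ITERATIONS:
            params = SAParams(
                spf=SWEEP_SA_SPF, n_iterations=it, n_restarts=10, seed=run_seed + it
            )
            best, _ = run_restarts(prob, params)
            if best.feasible:
                gaps[it].append(
                    (best.total_cost - opt.total_cost) / opt.total_cost
                )
        spf0 = SAParams(spf=0.0, n_iterations=10_000, n_restarts=1, seed=run_seed)
        best0, _ = run_restarts(prob, spf0)
        if best0.x.sum() == 0:
            n_spf0_empty += 1
        spf125 = SAParams(
            spf=125.0, n_iterations=10_000, n_restarts=10, seed=run_seed + 7
        )
        best125, _ = run_restarts(prob, spf125)
        if best125.feasible:
            n_spf125_met += 1
    return {
        "n_instances": n_instances,
        "median_gap_pct": {
            it: float(np.median(gaps[it]) * 100.0) if gaps[it] else np.nan
            for it in DESK_SA_ITERATIONS
        },
        "n_feasible": {it: len(gaps[it]) for it in DESK_SA_ITERATIONS},
        "spf0_empty_rate": n_spf0_empty / n_instances,
        "spf125_target_rate": n_spf125_met / n_instances,
    }
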