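"""Exact integer linear programming for the minimum-set problem.

The formulation: binary x_i selects unit i; the objective

    min  sum_i c_i x_i  +  b * ( sum_i B_i x_i - 2 sum_{i<j} v_ij y_ij )

subject to the representation constraints sum_i r_ij x_i >= T_j for every
feature j. The boundary term is the exposed perimeter of the selection,
which is quadratic in x; it is linearized with one auxiliary variable
y_ij per adjacent pair standing in for x_i * x_j, constrained by
y_ij <= x_i and y_ij <= x_j. Because the objective rewards large y
(coefficient -2 b v_ij < 0), y_ij is tight at min(x_i, x_j) in any
optimum, so the linear objective equals the true quadratic one and the y
variables may be declared continuous in [0, 1] without changing optima.

Solved through a small pluggable backend layer; the wired open-source
backend is HiGHS via :func:`scipy.optimize.milp`. Default gap tolerance
is 0 (prove global optimality), since the point of the exact route is a
certified optimum. A brute-force enumerator serves as an independent
oracle on small instances.
"""

from __future__ import annotations

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp

from .problem import ConservationProblem, Solution, evaluate

__all__ = [
    "MilpModel",
    "InfeasibleProblemError",
    "build_milp",
    "solve_milp",
    "brute_force",
    "BACKENDS",
]


class InfeasibleProblemError(ValueError):
    """Raised when no selection can satisfy the representation targets."""

    def __init__(self, message: str, features: list[str] | None = None):
        super().__init__(message)
        self.features = features or []


class MilpModel:
    """Solver-agnostic description of the linear program.

    Variables are ordered x_0..x_{N-1} then (when b > 0) one y per
    boundary pair. Constraints are stored as a single sparse matrix with
    lower/upper row bounds; the sense is always minimization.
    """

    def __init__(
        self,
        problem: ConservationProblem,
        objective: np.ndarray,
        constraint_matrix: sparse.csr_matrix,
        row_lower: np.ndarray,
        row_upper: np.ndarray,
        integrality: np.ndarray,
        var_lower: np.ndarray,
        var_upper: np.ndarray,
        gap_tolerance: float = 0.0,
    ):
        self.problem = problem
        self.objective = objective
        self.constraint_matrix = constraint_matrix
        self.row_lower = row_lower
        self.row_upper = row_upper
        self.integrality = integrality
        self.var_lower = var_lower
        self.var_upper = var_upper
        self.gap_tolerance = gap_tolerance

    @property
    def n_units(self) -> int:
        return self.problem.n_units

    @property
    def n_pair_vars(self) -> int:
        return len(self.objective) - self.problem.n_units


def _check_achievable(problem: ConservationProblem) -> None:
    totals = problem.amounts.sum(axis=0)
    bad = np.where(problem.targets > totals * (1 + 1e-9) + 1e-12)[0]
    if bad.size:
        names = [problem.feature_ids[j] for j in bad]
        raise InfeasibleProblemError(
            f"targets unreachable even selecting all units for features {names}",
            features=names,
        )


def build_milp(problem: ConservationProblem) -> MilpModel:
    """Assemble the MILP for a problem.

    With ``blm == 0`` no auxiliary variables or linearization rows are
    emitted — the model is the plain set-cover-style program.
    """
    _check_achievable(problem)
    n = problem.n_units
    m = problem.n_features
    b = problem.blm
    use_boundary = b > 0 and len(problem.boundary_pairs) > 0
    p = len(problem.boundary_pairs) if use_boundary else 0

    obj = np.concatenate(
        [
            problem.cost + (b * problem.total_perimeter if use_boundary else 0.0),
            -2.0 * b * problem.boundary_lengths if use_boundary else np.empty(0),
        ]
    )

    # representation rows: R^T x >= T
    target_rows = sparse.hstack(
        [sparse.csr_matrix(problem.amounts.T), sparse.csr_matrix((m, p))],
        format="csr",
    )
    blocks = [target_rows]
    lower = [problem.targets]
    upper = [np.full(m, np.inf)]

    if use_boundary:
        # y_ij - x_i <= 0 and y_ij - x_j <= 0
        rows = np.repeat(np.arange(2 * p), 2)
        cols = np.empty(4 * p, dtype=int)
        data = np.empty(4 * p)
        pair_i = problem.boundary_pairs[:, 0]
        pair_j = problem.boundary_pairs[:, 1]
        y_idx = n + np.arange(p)
        cols[0::4], cols[1::4] = y_idx, pair_i
        cols[2::4], cols[3::4] = y_idx, pair_j
        data[0::4] = data[2::4] = 1.0
        data[1::4] = data[3::4] = -1.0
        lin = sparse.csr_matrix((data, (rows, cols)), shape=(2 * p, n + p))
        blocks.append(lin)
        lower.append(np.full(2 * p, -np.inf))
        upper.append(np.zeros(2 * p))

    a_mat = sparse.vstack(blocks, format="csr")
    integrality = np.concatenate([np.ones(n), np.zeros(p)])  # x binary, y continuous
    var_lower = np.zeros(n + p)
    var_upper = np.ones(n + p)
    return MilpModel(
        problem=problem,
        objective=obj,
        constraint_matrix=a_mat,
        row_lower=np.concatenate(lower),
        row_upper=np.concatenate(upper),
        integrality=integrality,
        var_lower=var_lower,
        var_upper=var_upper,
    )


def _solve_highs(model: MilpModel, gap_tolerance: float, time_limit: float | None):
    options: dict = {"mip_rel_gap": gap_tolerance, "presolve": True}
    if time_limit is not None:
        options["time_limit"] = float(time_limit)
    return milp(
        c=model.objective,
        constraints=LinearConstraint(
            model.constraint_matrix, model.row_lower, model.row_upper
        ),
        integrality=model.integrality,
        bounds=Bounds(model.var_lower, model.var_upper),
        options=options,
    )


BACKENDS = {"highs": _solve_highs}


def solve_milp(
    model: MilpModel,
    backend: str = "highs",
    gap_tolerance: float = 0.0,
    time_limit: float | None = None,
) -> Solution:
    """Solve a built model and evaluate the selected units.

    With ``gap_tolerance=0`` the returned objective is the certified
    global optimum. A time limit returns the best incumbent with the
    optimality flag set False; proven infeasibility raises
    :class:`InfeasibleProblemError` naming the binding features.
    """
    if backend not in BACKENDS:
        raise ValueError(f"unknown backend {backend!r}; available: {sorted(BACKENDS)}")
    res = BACKENDS[backend](model, gap_tolerance, time_limit)

    problem = model.problem
    if res.status == 2:  # proven infeasible
        raise InfeasibleProblemError(
            "MILP proven infeasible: no selection meets all representation "
            f"targets ({[problem.feature_ids[j] for j in range(problem.n_features)]})"
        )
    if res.x is None:
        raise RuntimeError(f"MILP terminated without an incumbent: {res.message}")

    x = np.rint(res.x[: problem.n_units]).astype(int)
    optimal = bool(res.status == 0)
    sol = evaluate(
        problem,
        x,
        provenance={
            "solver": f"ilp/{backend}",
            "gap_tolerance": gap_tolerance,
            "optimal": optimal,
            "mip_gap": float(getattr(res, "mip_gap", np.nan)),
            "dual_bound": float(getattr(res, "mip_dual_bound", np.nan)),
            "status": int(res.status),
        },
    )
    return sol


def brute_force(problem: ConservationProblem, cap: int = 20) -> Solution:
    """Exhaustive enumeration oracle for small instances.

    Enumerates all 2^N selections, keeps feasible ones, and returns the
    minimizer of the exact (quadratic-boundary) objective
    ``cost + blm * boundary_length``. Ties are broken in favour of the
    lexicographically smallest selection vector (x_0 first). Refuses
    instances above ``cap`` units.
    """
    n = problem.n_units
    if n > cap:
        raise ValueError(f"brute force refused: {n} units exceeds cap {cap}")
    _check_achievable(problem)

    best_obj = np.inf
    best_x: np.ndarray | None = None
    chunk = 1 << 16
    bit_cols = np.arange(n)
    pair_i = problem.boundary_pairs[:, 0]
    pair_j = problem.boundary_pairs[:, 1]

    for start in range(0, 1 << n, chunk):
        masks = np.arange(start, min(start + chunk, 1 << n), dtype=np.int64)
        x_all = ((masks[:, None] >> bit_cols[None, :]) & 1).astype(float)
        held = x_all @ problem.amounts
        feas = np.all(
            held >= problem.targets - 1e-9 * np.maximum(problem.targets, 1.0), axis=1
        )
        if not feas.any():
            continue
        xf = x_all[feas]
        obj = xf @ problem.cost
        if problem.blm > 0:
            blen = xf @ problem.total_perimeter
            if len(pair_i):
                blen = blen - 2.0 * (
                    (xf[:, pair_i] * xf[:, pair_j]) @ problem.boundary_lengths
                )
            obj = obj + problem.blm * blen
        k = int(np.argmin(obj))
        # within the chunk, resolve ties toward the lexicographically
        # smallest selection vector
        tied = np.where(obj <= obj[k] + 1e-9 * max(abs(obj[k]), 1.0))[0]
        cand_x = min((tuple(xf[t].astype(int)) for t in tied))
        cand_obj = float(min(obj[tied]))
        if cand_obj < best_obj - 1e-9 * max(abs(best_obj), 1.0) or (
            abs(cand_obj - best_obj) <= 1e-9 * max(abs(best_obj), 1.0)
            and best_x is not None
            and cand_x < tuple(best_x)
        ):
            best_obj = cand_obj
            best_x = np.asarray(cand_x, dtype=int)
        elif best_x is None:
            best_obj = cand_obj
            best_x = np.asarray(cand_x, dtype=int)

    if best_x is None:
        raise InfeasibleProblemError("no feasible selection exists")
    return evaluate(
        problem,
        best_x,
        provenance={"solver": "brute_force", "optimal": True, "gap_tolerance": 0.0},
    )
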