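"""Minimum-set reserve-selection problems and solution evaluation.

The minimum-set problem: choose a subset of N planning units, each with a
positive cost c_i and holding a nonnegative amount r_ij of each of M
conservation features, so that the selected amounts meet a representation
target T_j for every feature, at minimum total cost. An optional boundary
penalty (weight b, the "boundary length modifier" or BLM) rewards
spatially compact selections by charging the exposed perimeter of the
selected set.

Two objective conventions are evaluated for any candidate selection x:

* ``ilp_objective`` — the exact formulation's objective,
  ``sum_i c_i x_i + b * boundary_length(x)``;
* ``sa_objective`` — the Marxan-style penalized objective, which adds
  ``sum_j spf_j * penalty_j * shortfall_j / T_j`` for unmet targets, so
  infeasible selections are admissible but penalized.

Boundary convention: rook (4-neighbour) adjacency; a unit's exposed edges
toward unselected neighbours AND toward the study-area exterior both
count, so an empty selection has boundary length 0 and a single selected
unit has its full perimeter. Exterior edges can be excluded when building
the boundary structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "ConservationProblem",
    "Solution",
    "compute_targets",
    "build_boundary",
    "boundary_length",
    "evaluate",
    "problem_from_landscape",
]

_REL_TOL = 1e-9


@dataclass
class ConservationProblem:
    """Planning units, feature amounts, targets and boundary structure.

    Attributes
    ----------
    unit_ids : (N,) int array — external labels, arbitrary positive ints.
    cost : (N,) float array — positive acquisition cost c_i per unit.
    amounts : (N, M) float array — amount r_ij of feature j in unit i.
    targets : (M,) float array — representation target T_j per feature.
    boundary_pairs : (P, 2) int array — rook-adjacent index pairs, i < j.
    boundary_lengths : (P,) float array — shared edge length v_ij per pair.
    total_perimeter : (N,) float array — B_i, each unit's total edge
        length (shared + exterior).
    blm : float — boundary length modifier b >= 0.
    feature_ids : labels, one per feature.
    target_proportion : the proportion p used to derive targets, if any.
    """

    unit_ids: np.ndarray
    cost: np.ndarray
    amounts: np.ndarray
    targets: np.ndarray
    boundary_pairs: np.ndarray = field(default_factory=lambda: np.empty((0, 2), dtype=int))
    boundary_lengths: np.ndarray = field(default_factory=lambda: np.empty(0))
    total_perimeter: np.ndarray | None = None
    blm: float = 0.0
    feature_ids: list[str] = field(default_factory=list)
    target_proportion: float | None = None

    def __post_init__(self) -> None:
        self.unit_ids = np.asarray(self.unit_ids, dtype=int)
        self.cost = np.asarray(self.cost, dtype=float)
        self.amounts = np.atleast_2d(np.asarray(self.amounts, dtype=float))
        self.targets = np.asarray(self.targets, dtype=float)
        self.boundary_pairs = np.asarray(self.boundary_pairs, dtype=int).reshape(-1, 2)
        self.boundary_lengths = np.asarray(self.boundary_lengths, dtype=float)
        if self.total_perimeter is None:
            # without geometry, exposure defaults to the shared edges only
            self.total_perimeter = self._shared_edge_sums()
        else:
            self.total_perimeter = np.asarray(self.total_perimeter, dtype=float)
        if not self.feature_ids:
            self.feature_ids = [f"feature_{j:03d}" for j in range(self.n_features)]
        self.validate()

    def _shared_edge_sums(self) -> np.ndarray:
        shared = np.zeros(len(self.cost))
        if len(self.boundary_pairs):
            np.add.at(shared, self.boundary_pairs[:, 0], self.boundary_lengths)
            np.add.at(shared, self.boundary_pairs[:, 1], self.boundary_lengths)
        return shared

    def validate(self) -> None:
        n, m = self.amounts.shape
        if self.cost.shape != (n,) or self.unit_ids.shape != (n,):
            raise ValueError("cost/unit_ids length does not match amounts rows")
        if self.targets.shape != (m,):
            raise ValueError("targets length does not match amounts columns")
        if len(self.feature_ids) != m:
            raise ValueError("feature_ids length does not match amounts columns")
        if np.any(self.cost <= 0) or not np.all(np.isfinite(self.cost)):
            raise ValueError("all unit costs must be strictly positive and finite")
        if np.any(self.amounts < 0):
            raise ValueError("feature amounts must be nonnegative")
        totals = self.amounts.sum(axis=0)
        bad = np.where(self.targets > totals * (1 + _REL_TOL) + 1e-12)[0]
        if bad.size:
            names = [self.feature_ids[j] for j in bad]
            raise ValueError(
                f"targets exceed landscape totals for features {names}; "
                "the problem is infeasible even selecting every unit"
            )
        if len(self.boundary_pairs) != len(self.boundary_lengths):
            raise ValueError("boundary_pairs and boundary_lengths lengths differ")
        if len(self.boundary_pairs):
            if np.any(self.boundary_pairs[:, 0] == self.boundary_pairs[:, 1]):
                raise ValueError("boundary structure must not contain self-pairs")
            if np.any(self.boundary_lengths < 0):
                raise ValueError("boundary lengths must be nonnegative")
        shared = self._shared_edge_sums()
        if np.any(self.total_perimeter < shared - 1e-9 * np.maximum(shared, 1)):
            raise ValueError("total_perimeter must be >= the sum of shared edges")
        if self.blm < 0:
            raise ValueError("blm must be nonnegative")

    @property
    def n_units(self) -> int:
        return self.amounts.shape[0]

    @property
    def n_features(self) -> int:
        return self.amounts.shape[1]


@dataclass
class Solution:
    """A binary selection with its evaluated quantities.

    ``feasible`` holds iff every per-feature shortfall is zero.
    ``sa_objective`` is None when no penalty parameters were supplied.
    ``provenance`` records solver name, seed and optimality metadata.
    """

    x: np.ndarray
    total_cost: float
    boundary_length: float
    shortfalls: np.ndarray
    n_targets_met: int
    feasible: bool
    ilp_objective: float
    sa_objective: float | None = None
    provenance: dict = field(default_factory=dict)


def compute_targets(amounts: np.ndarray, proportion: float) -> np.ndarray:
    """Proportional representation targets: T_j = proportion * sum_i r_ij."""
    if not (0.0 < proportion <= 1.0):
        raise ValueError(f"target proportion must be in (0, 1], got {proportion}")
    amounts = np.atleast_2d(np.asarray(amounts, dtype=float))
    if np.any(amounts < 0):
        raise ValueError("feature amounts must be nonnegative")
    return proportion * amounts.sum(axis=0)


def build_boundary(
    n_rows: int,
    n_cols: int,
    edge_length: float = 1.0,
    include_exterior: bool = True,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Rook-adjacency boundary structure for a rectangular unit grid.

    Returns ``(pairs, lengths, total_perimeter)``: index pairs (i < j,
    row-major 0-based) for horizontally/vertically adjacent units, the
    shared edge length v_ij (= edge_length) per pair, and per-unit total
    perimeter B_i. With ``include_exterior`` (the default) B_i is the full
    4-sided perimeter, so edges on the study-area rim count as exposed;
    otherwise B_i counts shared edges only.
    """
    if n_rows < 1 or n_cols < 1:
        raise ValueError("grid dimensions must be >= 1")
    if edge_length <= 0:
        raise ValueError("edge_length must be positive")
    pairs = []
    for r in range(n_rows):
        for c in range(n_cols):
            i = r * n_cols + c
            if c + 1 < n_cols:
                pairs.append((i, i + 1))
            if r + 1 < n_rows:
                pairs.append((i, i + n_cols))
    pairs_arr = np.asarray(pairs, dtype=int).reshape(-1, 2)
    lengths = np.full(len(pairs_arr), float(edge_length))
    n = n_rows * n_cols
    if include_exterior:
        perimeter = np.full(n, 4.0 * edge_length)
    else:
        perimeter = np.zeros(n)
        if len(pairs_arr):
            np.add.at(perimeter, pairs_arr[:, 0], lengths)
            np.add.at(perimeter, pairs_arr[:, 1], lengths)
    return pairs_arr, lengths, perimeter


def boundary_length(problem: ConservationProblem, x: np.ndarray) -> float:
    """Exposed perimeter of a selection.

    The quadratic form ``sum_i B_i x_i - 2 sum_{i<j} v_ij x_i x_j``:
    each selected unit contributes its total perimeter and each
    selected-selected shared edge is interior, hence subtracted twice.
    """
    x = np.asarray(x, dtype=float)
    total = float(problem.total_perimeter @ x)
    if len(problem.boundary_pairs):
        both = x[problem.boundary_pairs[:, 0]] * x[problem.boundary_pairs[:, 1]]
        total -= 2.0 * float(problem.boundary_lengths @ both)
    return total


def _as_binary(x: Sequence[float] | np.ndarray, n: int) -> np.ndarray:
    x = np.asarray(x)
    if x.shape != (n,):
        raise ValueError(f"selection vector has shape {x.shape}, expected ({n},)")
    xb = x.astype(float)
    if not np.all((xb == 0) | (xb == 1)):
        raise ValueError("selection vector must be binary")
    return xb


def evaluate(
    problem: ConservationProblem,
    x: Sequence[float] | np.ndarray,
    spf: float | np.ndarray | None = None,
    feature_penalties: np.ndarray | None = None,
    provenance: dict | None = None,
) -> Solution:
    """Evaluate a candidate selection under both objectives.

    ``spf`` (scalar or per-feature) and ``feature_penalties`` activate the
    Marxan-style penalized objective; the shortfall is normalized by the
    target (fraction of target unmet) so the penalty factor is unitless.
    Features with T_j = 0 contribute no penalty and always count as met.
    """
    xb = _as_binary(x, problem.n_units)
    total_cost = float(problem.cost @ xb)
    blen = boundary_length(problem, xb)
    held = problem.amounts.T @ xb
    shortfalls = np.maximum(0.0, problem.targets - held)
    # tolerance: floating accumulation must not flag met targets as missed
    met = shortfalls <= _REL_TOL * np.maximum(problem.targets, 1.0)
    shortfalls = np.where(met, 0.0, shortfalls)
    feasible = bool(met.all())
    ilp_obj = total_cost + problem.blm * blen

    sa_obj = None
    if spf is not None and feature_penalties is not None:
        spf_arr = np.broadcast_to(np.asarray(spf, dtype=float), (problem.n_features,))
        if np.any(spf_arr < 0):
            raise ValueError("spf must be nonnegative")
        pen = np.asarray(feature_penalties, dtype=float)
        if np.any(pen < 0):
            raise ValueError("feature penalties must be nonnegative")
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(problem.targets > 0, shortfalls / problem.targets, 0.0)
        sa_obj = ilp_obj + float((spf_arr * pen * ratio).sum())

    return Solution(
        x=xb.astype(int),
        total_cost=total_cost,
        boundary_length=blen,
        shortfalls=shortfalls,
        n_targets_met=int(met.sum()),
        feasible=feasible,
        ilp_objective=ilp_obj,
        sa_objective=sa_obj,
        provenance=provenance or {},
    )


def problem_from_landscape(
    landscape,
    target_proportion: float,
    blm: float = 0.0,
    include_exterior: bool = True,
) -> ConservationProblem:
    """Assemble a problem from an (already aggregated) landscape.

    Each raster cell becomes one planning unit (row-major, ids 1..N);
    feature amounts are the per-cell occupancy values, targets a fixed
    proportion of each feature's landscape total.
    """
    n = landscape.n_cells
    amounts = np.column_stack([f.ravel() for f in landscape.features])
    targets = compute_targets(amounts, target_proportion)
    pairs, lengths, perimeter = build_boundary(
        landscape.n_rows,
        landscape.n_cols,
        edge_length=landscape.cell_size,
        include_exterior=include_exterior,
    )
    return ConservationProblem(
        unit_ids=np.arange(1, n + 1),
        cost=landscape.cost.ravel(),
        amounts=amounts,
        targets=targets,
        boundary_pairs=pairs,
        boundary_lengths=lengths,
        total_perimeter=perimeter,
        blm=blm,
        feature_ids=list(landscape.feature_ids),
        target_proportion=target_proportion,
    )
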