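"""Readers and writers for the Marxan tabular input dialect.

Marxan-compatible planning tools exchange problems as four plain-text
tables in one directory:

* ``pu.dat``     — planning units: ``id,cost,status``
* ``spec.dat``   — features: ``id,target,spf,name``
* ``puvspr.dat`` — amounts: ``species,pu,amount`` (sorted by pu, then species)
* ``bound.dat``  — shared boundaries: ``id1,id2,boundary`` (optional)

Both comma- and tab-delimited files are accepted on read (the delimiter
is sniffed from the header line); output is always comma-delimited with a
header. Numeric fields are written with 10 significant digits, and all
writers are deterministic, so a write -> read -> write round trip is
byte-identical. Referential integrity (dangling ids, self-pairs,
duplicate pairs, negative costs) is validated on read with file and line
numbers in the error message.

Unit ``status`` values other than 0 (locked-in/locked-out units) are
rejected. ``bound.dat`` carries shared edges only, so a problem read from
a bundle has no exterior-edge information: its per-unit exposure is the
sum of its shared edges.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .problem import ConservationProblem, Solution

__all__ = [
    "MarxanInputBundle",
    "MarxanFormatError",
    "read_marxan",
    "write_marxan",
    "problem_from_bundle",
    "bundle_from_problem",
    "write_solution",
    "read_solution",
]


class MarxanFormatError(ValueError):
    """A malformed or referentially inconsistent Marxan bundle."""


@dataclass
class MarxanInputBundle:
    """The four input tables plus the dialect observed on read."""

    pu: pd.DataFrame
    spec: pd.DataFrame
    puvspr: pd.DataFrame
    bound: pd.DataFrame | None = None
    delimiter: str = ","

    def validate(self) -> None:
        pu_ids = set(self.pu.id)
        spec_ids = set(self.spec.id)
        if len(pu_ids) != len(self.pu):
            raise MarxanFormatError("pu.dat: duplicate planning-unit ids")
        if len(spec_ids) != len(self.spec):
            raise MarxanFormatError("spec.dat: duplicate feature ids")
        if (self.pu.cost <= 0).any():
            row = int(np.argmax(self.pu.cost.to_numpy() <= 0))
            raise MarxanFormatError(
                f"pu.dat line {row + 2}: cost must be strictly positive "
                f"(id {int(self.pu.id.iloc[row])})"
            )
        if (self.pu.status != 0).any():
            row = int(np.argmax(self.pu.status.to_numpy() != 0))
            raise MarxanFormatError(
                f"pu.dat line {row + 2}: status {int(self.pu.status.iloc[row])} "
                "not supported (only status 0)"
            )
        for col, universe, fname in (
            ("pu", pu_ids, "puvspr.dat"),
            ("species", spec_ids, "puvspr.dat"),
        ):
            vals = self.puvspr[col].to_numpy()
            bad = ~np.isin(vals, list(universe))
            if bad.any():
                row = int(np.argmax(bad))
                raise MarxanFormatError(
                    f"{fname} line {row + 2}: dangling {col} id {int(vals[row])}"
                )
        if (self.puvspr.amount < 0).any():
            row = int(np.argmax(self.puvspr.amount.to_numpy() < 0))
            raise MarxanFormatError(f"puvspr.dat line {row + 2}: negative amount")
        if self.bound is not None and len(self.bound):
            b = self.bound
            for col in ("id1", "id2"):
                vals = b[col].to_numpy()
                bad = ~np.isin(vals, list(pu_ids))
                if bad.any():
                    row = int(np.argmax(bad))
                    raise MarxanFormatError(
                        f"bound.dat line {row + 2}: dangling {col} id {int(vals[row])}"
                    )
            self_pair = (b.id1 == b.id2).to_numpy()
            if self_pair.any():
                row = int(np.argmax(self_pair))
                raise MarxanFormatError(
                    f"bound.dat line {row + 2}: self-pair id {int(b.id1.iloc[row])}"
                )
            if (b.boundary < 0).any():
                row = int(np.argmax(b.boundary.to_numpy() < 0))
                raise MarxanFormatError(f"bound.dat line {row + 2}: negative boundary")
            canon = pd.DataFrame(
                {"a": np.minimum(b.id1, b.id2), "b": np.maximum(b.id1, b.id2)}
            )
            if canon.duplicated().any():
                row = int(np.argmax(canon.duplicated().to_numpy()))
                raise MarxanFormatError(
                    f"bound.dat line {row + 2}: duplicate pair "
                    f"({int(b.id1.iloc[row])}, {int(b.id2.iloc[row])})"
                )


_SCHEMAS = {
    "pu.dat": ["id", "cost", "status"],
    "spec.dat": ["id", "target", "spf", "name"],
    "puvspr.dat": ["species", "pu", "amount"],
    "bound.dat": ["id1", "id2", "boundary"],
}


def _read_table(path: Path) -> tuple[pd.DataFrame, str]:
    text = path.read_text()
    header = text.splitlines()[0] if text else ""
    delim = "\t" if "\t" in header else ","
    df = pd.read_csv(io.StringIO(text), sep=delim)
    df.columns = [c.strip().lower() for c in df.columns]
    expected = _SCHEMAS[path.name]
    unknown = [c for c in df.columns if c not in expected]
    if unknown:
        raise MarxanFormatError(f"{path.name}: unknown column(s) {unknown}")
    missing = [c for c in expected if c not in df.columns and (path.name, c) != ("spec.dat", "name")]
    if missing:
        raise MarxanFormatError(f"{path.name}: missing column(s) {missing}")
    return df, delim


def read_marxan(directory: str | Path) -> tuple[MarxanInputBundle, ConservationProblem]:
    """Read a Marxan bundle and map it to a ConservationProblem.

    ``spec.target`` is used directly as the per-feature target; the
    ``spf`` column is preserved on the bundle for annealing runs. A
    missing ``bound.dat`` forces the boundary weight to 0 with a warning.
    """
    directory = Path(directory)
    for fname in ("pu.dat", "spec.dat", "puvspr.dat"):
        if not (directory / fname).exists():
            raise MarxanFormatError(f"missing mandatory file {fname} in {directory}")
    pu, delim = _read_table(directory / "pu.dat")
    spec, _ = _read_table(directory / "spec.dat")
    puvspr, _ = _read_table(directory / "puvspr.dat")
    bound = None
    if (directory / "bound.dat").exists():
        bound, _ = _read_table(directory / "bound.dat")
    else:
        import warnings

        warnings.warn("bound.dat missing: boundary weight forced to 0", stacklevel=2)
    if "name" not in spec.columns:
        spec = spec.assign(name=[f"feature_{i}" for i in spec.id])
    bundle = MarxanInputBundle(pu=pu, spec=spec, puvspr=puvspr, bound=bound, delimiter=delim)
    bundle.validate()
    return bundle, problem_from_bundle(bundle)


def problem_from_bundle(bundle: MarxanInputBundle) -> ConservationProblem:
    pu = bundle.pu.sort_values("id", kind="stable").reset_index(drop=True)
    spec = bundle.spec.sort_values("id", kind="stable").reset_index(drop=True)
    uidx = {int(i): k for k, i in enumerate(pu.id)}
    fidx = {int(i): k for k, i in enumerate(spec.id)}
    amounts = np.zeros((len(pu), len(spec)))
    for s, u, a in bundle.puvspr.itertuples(index=False):
        amounts[uidx[int(u)], fidx[int(s)]] += float(a)
    if bundle.bound is not None and len(bundle.bound):
        i = np.array([uidx[int(v)] for v in bundle.bound.id1])
        j = np.array([uidx[int(v)] for v in bundle.bound.id2])
        lo, hi = np.minimum(i, j), np.maximum(i, j)
        order = np.lexsort((hi, lo))
        pairs = np.column_stack([lo, hi])[order]
        lengths = bundle.bound.boundary.to_numpy(dtype=float)[order]
    else:
        pairs = np.empty((0, 2), dtype=int)
        lengths = np.empty(0)
    return ConservationProblem(
        unit_ids=pu.id.to_numpy(dtype=int),
        cost=pu.cost.to_numpy(dtype=float),
        amounts=amounts,
        targets=spec.target.to_numpy(dtype=float),
        boundary_pairs=pairs,
        boundary_lengths=lengths,
        total_perimeter=None,  # exterior exposure is not representable in the dialect
        feature_ids=[str(n) for n in spec.name],
    )


def _fmt(value: float) -> str:
    return f"{float(value):.10g}"


def _write_table(path: Path, df: pd.DataFrame, float_cols: set[str]) -> None:
    cols = list(df.columns)
    with open(path, "w", newline="\n") as fh:
        fh.write(",".join(cols) + "\n")
        for row in df.itertuples(index=False):
            parts = []
            for col, val in zip(cols, row):
                parts.append(_fmt(val) if col in float_cols else str(val))
            fh.write(",".join(parts) + "\n")


def bundle_from_problem(
    problem: ConservationProblem, spf: float | np.ndarray = 25.0
) -> MarxanInputBundle:
    spf_arr = np.broadcast_to(np.asarray(spf, dtype=float), (problem.n_features,))
    pu = pd.DataFrame(
        {"id": problem.unit_ids, "cost": problem.cost, "status": 0}
    ).sort_values("id", kind="stable").reset_index(drop=True)
    feature_ids = np.arange(1, problem.n_features + 1)
    spec = pd.DataFrame(
        {
            "id": feature_ids,
            "target": problem.targets,
            "spf": spf_arr,
            "name": problem.feature_ids,
        }
    )
    ui, fj = np.nonzero(problem.amounts > 0)
    puvspr = pd.DataFrame(
        {
            "species": feature_ids[fj],
            "pu": problem.unit_ids[ui],
            "amount": problem.amounts[ui, fj],
        }
    ).sort_values(["pu", "species"], kind="stable").reset_index(drop=True)
    if len(problem.boundary_pairs):
        id1 = problem.unit_ids[problem.boundary_pairs[:, 0]]
        id2 = problem.unit_ids[problem.boundary_pairs[:, 1]]
        lo, hi = np.minimum(id1, id2), np.maximum(id1, id2)
        bound = pd.DataFrame(
            {"id1": lo, "id2": hi, "boundary": problem.boundary_lengths}
        ).sort_values(["id1", "id2"], kind="stable").reset_index(drop=True)
    else:
        bound = pd.DataFrame(columns=["id1", "id2", "boundary"])
    return MarxanInputBundle(pu=pu, spec=spec, puvspr=puvspr, bound=bound)


def write_marxan(
    source: ConservationProblem | MarxanInputBundle,
    directory: str | Path,
    spf: float | np.ndarray = 25.0,
) -> None:
    """Write the four tables, comma-delimited, canonically sorted.

    ``bound.dat`` is always written when boundary structure exists —
    boundary data is geometric, not dependent on the penalty weight.
    """
    bundle = (
        source
        if isinstance(source, MarxanInputBundle)
        else bundle_from_problem(source, spf=spf)
    )
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    pu = bundle.pu.sort_values("id", kind="stable")
    _write_table(directory / "pu.dat", pu[["id", "cost", "status"]], {"cost"})
    spec = bundle.spec.sort_values("id", kind="stable")
    _write_table(directory / "spec.dat", spec[["id", "target", "spf", "name"]], {"target", "spf"})
    puvspr = bundle.puvspr.sort_values(["pu", "species"], kind="stable")
    _write_table(directory / "puvspr.dat", puvspr[["species", "pu", "amount"]], {"amount"})
    if bundle.bound is not None:
        b = bundle.bound
        if len(b):
            lo, hi = np.minimum(b.id1, b.id2), np.maximum(b.id1, b.id2)
            b = pd.DataFrame({"id1": lo, "id2": hi, "boundary": b.boundary})
            b = b.sort_values(["id1", "id2"], kind="stable")
        _write_table(directory / "bound.dat", b[["id1", "id2", "boundary"]], {"boundary"})


def write_solution(
    directory: str | Path, problem: ConservationProblem, solution: Solution
) -> None:
    """Solution CSV (unit_id, selected) plus a JSON metadata sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    with open(directory / "solution.csv", "w", newline="\n") as fh:
        fh.write("unit_id,selected\n")
        for uid, sel in zip(problem.unit_ids, solution.x):
            fh.write(f"{int(uid)},{int(sel)}\n")
    meta = {
        "total_cost": solution.total_cost,
        "boundary_length": solution.boundary_length,
        "ilp_objective": solution.ilp_objective,
        "sa_objective": solution.sa_objective,
        "n_targets_met": solution.n_targets_met,
        "n_features": problem.n_features,
        "feasible": solution.feasible,
        "provenance": {
            k: v for k, v in solution.provenance.items() if k != "objective_trace"
        },
    }
    (directory / "solution_meta.json").write_text(json.dumps(meta, indent=2) + "\n")


def read_solution(directory: str | Path) -> tuple[np.ndarray, dict]:
    directory = Path(directory)
    df = pd.read_csv(directory / "solution.csv")
    meta = json.loads((directory / "solution_meta.json").read_text())
    return df.selected.to_numpy(dtype=int), meta
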