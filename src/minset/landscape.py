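"""Synthetic landscapes for reserve-selection experiments.

Real minimum-set prioritization studies start from two kinds of raster
layers: per-cell acquisition *cost* (assessed land value — positive and
strongly right-skewed) and, for each conservation feature (typically a
species), a per-cell *occupancy probability* in [0, 1] that varies
smoothly across space. This module generates stand-in surfaces with the
same statistical structure so every downstream stage — problem assembly,
both solvers, the benchmark sweeps — is fully testable without any
external data.

Construction
------------
Spatially autocorrelated Gaussian fields are produced by smoothing white
noise with a Gaussian kernel whose bandwidth is the requested correlation
range, then re-standardizing to zero mean / unit variance. Cost surfaces
are the exponential of such a field (lognormal marginals); occupancy
surfaces are a logistic squash of such a field, with the offset solved
numerically so the realized landscape-mean occupancy matches a requested
prevalence.

Planning units are formed from the fine grid by block aggregation:
costs are *summed*, occupancy is *averaged* over each block.

Conventions: rasters are 2-D arrays, origin at the top-left, cells
indexed row-major and 0-based. Everything is a pure function of its
parameters and seed; feature ``k`` uses a sub-seed derived from
``(seed, k)`` so adding features never perturbs existing ones.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.optimize import brentq
from scipy.special import expit

__all__ = [
    "Landscape",
    "generate_cost_surface",
    "generate_feature_surfaces",
    "generate_landscape",
    "aggregate",
    "aggregate_landscape",
    "write_raster_csv",
    "read_raster_csv",
    "write_raster_long_csv",
    "save_landscape",
    "load_landscape",
]

# sub-stream tags keeping cost and feature RNG streams disjoint
_COST_STREAM = 0
_FEATURE_STREAM = 1


@dataclass(frozen=True)
class Landscape:
    """A cost surface plus a stack of feature occupancy surfaces.

    Attributes
    ----------
    n_rows, n_cols : int
        Raster dimensions (cells).
    cell_size : float
        Edge length of one cell, in arbitrary length units.
    cost : ndarray of shape (n_rows, n_cols)
        Strictly positive per-cell cost.
    features : list of ndarray
        Per-feature occupancy surfaces, each shaped like ``cost`` with
        values in [0, 1].
    feature_ids : list of str
        Ordered labels, one per feature surface.
    seed : int
        RNG seed recorded at creation (generation is deterministic in it).
    """

    n_rows: int
    n_cols: int
    cost: np.ndarray
    features: list[np.ndarray] = field(default_factory=list)
    feature_ids: list[str] = field(default_factory=list)
    cell_size: float = 1.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.cost.shape != (self.n_rows, self.n_cols):
            raise ValueError(
                f"cost shape {self.cost.shape} != ({self.n_rows}, {self.n_cols})"
            )
        if not np.all(np.isfinite(self.cost)) or np.any(self.cost <= 0):
            raise ValueError("cost values must be strictly positive and finite")
        if len(self.features) != len(self.feature_ids):
            raise ValueError(
                f"{len(self.features)} feature surfaces but "
                f"{len(self.feature_ids)} feature_ids"
            )
        for fid, surf in zip(self.feature_ids, self.features):
            if surf.shape != self.cost.shape:
                raise ValueError(f"feature {fid!r} shape mismatch")
            if np.any(surf < 0) or np.any(surf > 1):
                raise ValueError(f"feature {fid!r} has values outside [0, 1]")

    @property
    def n_features(self) -> int:
        return len(self.features)

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols


def _autocorrelated_field(
    n_rows: int, n_cols: int, correlation_range: float, rng: np.random.Generator
) -> np.ndarray:
    """Standardized Gaussian random field with the given correlation range.

    White noise smoothed by a Gaussian kernel (sigma = correlation_range,
    reflective boundaries), then re-standardized to zero mean and unit
    variance. ``correlation_range == 0`` yields plain white noise.
    """
    noise = rng.standard_normal((n_rows, n_cols))
    if correlation_range > 0:
        fld = gaussian_filter(noise, sigma=correlation_range, mode="reflect")
    else:
        fld = noise
    sd = fld.std()
    if sd == 0.0:  # single cell, or pathologically flat
        return np.zeros_like(fld)
    return (fld - fld.mean()) / sd


def _check_dims(n_rows: int, n_cols: int) -> None:
    if n_rows < 1 or n_cols < 1:
        raise ValueError(f"raster dimensions must be >= 1, got {n_rows}x{n_cols}")


def generate_cost_surface(
    n_rows: int,
    n_cols: int,
    correlation_range: float = 5.0,
    sigma_log: float = 1.0,
    mean_log: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Lognormal, spatially autocorrelated cost surface.

    Returns ``exp(mean_log + sigma_log * G)`` where ``G`` is a
    standardized autocorrelated Gaussian field, so the log-cost has
    empirical mean ``mean_log`` and empirical standard deviation
    ``sigma_log`` exactly. Right-skewed and strictly positive, matching
    assessed land values. Deterministic given the seed.
    """
    _check_dims(n_rows, n_cols)
    if correlation_range < 0:
        raise ValueError("correlation_range must be >= 0")
    if sigma_log < 0:
        raise ValueError("sigma_log must be >= 0")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), _COST_STREAM]))
    g = _autocorrelated_field(n_rows, n_cols, correlation_range, rng)
    return np.exp(mean_log + sigma_log * g)


def _solve_offset(g: np.ndarray, steepness: float, prevalence: float) -> float:
    """Offset q such that mean(logistic(steepness * (g - q))) == prevalence."""
    half = 40.0 / steepness  # logistic saturates well before |z| = 40
    lo, hi = float(g.min()) - half, float(g.max()) + half

    def gap(q: float) -> float:
        return float(expit(steepness * (g - q)).mean()) - prevalence

    return brentq(gap, lo, hi, xtol=1e-12)


def generate_feature_surfaces(
    n_features: int,
    n_rows: int,
    n_cols: int,
    correlation_range: float = 5.0,
    prevalence: float = 0.25,
    steepness: float = 2.0,
    seed: int = 0,
) -> list[np.ndarray]:
    """Occupancy-probability surfaces for ``n_features`` independent features.

    Each surface is ``logistic(steepness * (G_k - q_k))`` for an
    independent standardized autocorrelated field ``G_k``, with the offset
    ``q_k`` solved so the surface mean equals ``prevalence`` (to numerical
    tolerance). ``steepness`` controls how sharply occupancy transitions
    between strongholds and absences; in the ``steepness -> 0`` limit the
    surface is flat at 0.5. Feature ``k`` draws from a sub-seed derived
    from ``(seed, k)``.
    """
    if n_features < 1:
        raise ValueError("n_features must be >= 1")
    _check_dims(n_rows, n_cols)
    if not (0.0 < prevalence < 1.0):
        raise ValueError(f"prevalence must be in (0, 1), got {prevalence}")
    if correlation_range < 0:
        raise ValueError("correlation_range must be >= 0")
    if steepness < 0:
        raise ValueError("steepness must be >= 0")

    surfaces: list[np.ndarray] = []
    for k in range(n_features):
        rng = np.random.default_rng(
            np.random.SeedSequence([int(seed), _FEATURE_STREAM, k])
        )
        g = _autocorrelated_field(n_rows, n_cols, correlation_range, rng)
        if steepness == 0.0:
            surfaces.append(np.full_like(g, 0.5))
            continue
        q = _solve_offset(g, steepness, prevalence)
        surfaces.append(expit(steepness * (g - q)))
    return surfaces


def generate_landscape(
    n_features: int,
    n_rows: int,
    n_cols: int,
    correlation_range: float = 5.0,
    prevalence: float = 0.25,
    steepness: float = 2.0,
    cost_sigma_log: float = 1.0,
    cost_mean_log: float = 0.0,
    cell_size: float = 1.0,
    seed: int = 0,
) -> Landscape:
    """Generate a full synthetic landscape (cost + feature stack)."""
    cost = generate_cost_surface(
        n_rows, n_cols, correlation_range, cost_sigma_log, cost_mean_log, seed
    )
    features = generate_feature_surfaces(
        n_features, n_rows, n_cols, correlation_range, prevalence, steepness, seed
    )
    ids = [f"feature_{k:03d}" for k in range(n_features)]
    return Landscape(
        n_rows=n_rows,
        n_cols=n_cols,
        cost=cost,
        features=features,
        feature_ids=ids,
        cell_size=cell_size,
        seed=seed,
    )


def aggregate(
    surface: np.ndarray, factor: int, method: str, trim: bool = False
) -> np.ndarray:
    """Block-aggregate a raster by an integer factor.

    ``method='sum'`` (costs) conserves the surface total; ``method='mean'``
    (occupancy) keeps values in the original range. The factor must divide
    both dimensions unless ``trim=True``, in which case trailing rows and
    columns are discarded.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    if method not in ("sum", "mean"):
        raise ValueError(f"unknown aggregation method {method!r}")
    arr = np.asarray(surface, dtype=float)
    nr, nc = arr.shape
    if nr % factor or nc % factor:
        if not trim:
            raise ValueError(
                f"factor {factor} does not divide dimensions {nr}x{nc}; "
                "pass trim=True to discard trailing cells"
            )
        arr = arr[: nr - nr % factor, : nc - nc % factor]
        nr, nc = arr.shape
    blocks = arr.reshape(nr // factor, factor, nc // factor, factor)
    if method == "sum":
        return blocks.sum(axis=(1, 3))
    return blocks.mean(axis=(1, 3))


def aggregate_landscape(landscape: Landscape, factor: int, trim: bool = False) -> Landscape:
    """Aggregate a landscape to coarser planning units.

    Costs are summed and occupancy averaged over each ``factor x factor``
    block — the standard construction when planning units are coarser
    than the species/cost rasters.
    """
    cost = aggregate(landscape.cost, factor, "sum", trim=trim)
    feats = [aggregate(f, factor, "mean", trim=trim) for f in landscape.features]
    return Landscape(
        n_rows=cost.shape[0],
        n_cols=cost.shape[1],
        cost=cost,
        features=feats,
        feature_ids=list(landscape.feature_ids),
        cell_size=landscape.cell_size * factor,
        seed=landscape.seed,
    )


# ---------------------------------------------------------------------------
# plain-text raster I/O


def write_raster_csv(path: str | Path, surface: np.ndarray) -> None:
    """Write a raster as a CSV grid: one file row per raster row."""
    np.savetxt(path, np.asarray(surface, dtype=float), delimiter=",", fmt="%.10g")


def read_raster_csv(path: str | Path) -> np.ndarray:
    arr = np.loadtxt(path, delimiter=",", dtype=float)
    return np.atleast_2d(arr)


def write_raster_long_csv(path: str | Path, surface: np.ndarray) -> None:
    """Write a raster in long format: header ``cell_id,value``, row-major ids."""
    flat = np.asarray(surface, dtype=float).ravel()
    with open(path, "w") as fh:
        fh.write("cell_id,value\n")
        for i, v in enumerate(flat):
            fh.write(f"{i},{v:.10g}\n")


def save_landscape(landscape: Landscape, directory: str | Path) -> None:
    """Write cost, one CSV per feature, and a JSON manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_raster_csv(directory / "cost.csv", landscape.cost)
    for fid, surf in zip(landscape.feature_ids, landscape.features):
        write_raster_csv(directory / f"{fid}.csv", surf)
    manifest = {
        "n_rows": landscape.n_rows,
        "n_cols": landscape.n_cols,
        "cell_size": landscape.cell_size,
        "seed": landscape.seed,
        "feature_ids": list(landscape.feature_ids),
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")


def load_landscape(directory: str | Path) -> Landscape:
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    cost = read_raster_csv(directory / "cost.csv")
    features = [read_raster_csv(directory / f"{fid}.csv") for fid in manifest["feature_ids"]]
    return Landscape(
        n_rows=manifest["n_rows"],
        n_cols=manifest["n_cols"],
        cost=cost,
        features=features,
        feature_ids=list(manifest["feature_ids"]),
        cell_size=manifest["cell_size"],
        seed=manifest["seed"],
    )
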