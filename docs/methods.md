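# Methods

## The minimum-set model

A landscape is divided into N planning units. Unit *i* costs
c_i > 0 and holds r_ij ≥ 0 of feature *j* (j = 1..M). Targets are
proportional: T_j = p · Σ_i r_ij for a protection proportion
p ∈ (0, 1], so targets are achievable by construction (selecting
everything meets them). A selection x ∈ {0,1}^N is *feasible* when
Σ_i r_ij x_i ≥ T_j for every feature.

Spatial compactness enters through the exposed perimeter of the selected
set under rook (4-neighbour) adjacency,

    boundary(x) = Σ_i B_i x_i − 2 Σ_{i<j} v_ij x_i x_j ,

with v_ij the shared edge length of adjacent pairs and B_i the unit's
total edge length. **Convention:** edges on the study-area rim count as
exposed (B_i = 4·edge for every grid unit), so an empty selection has
boundary 0 and one selected unit has its full perimeter. `build_boundary`
can exclude exterior edges; cross-solver equality tests rely on a single
fixed convention. Problems read from Marxan bundles necessarily use
B_i = Σ_j v_ij because the dialect (no self-pairs in `bound.dat`) cannot
carry exterior exposure.

Two objectives are evaluated for any x:

* exact-route objective: cost(x) + b·boundary(x), minimized subject to
  the hard target constraints;
* penalized (annealer) objective: the same, plus
  Σ_j s_j · penalty_j · shortfall_j / T_j, where shortfall_j =
  max(0, T_j − held_j). The shortfall is normalized by the target so the
  species penalty factor s_j is unitless; features with T_j = 0 are
  always met and contribute nothing. The penalized objective dominates
  the exact one, with equality exactly on feasible selections — the
  hinge every dominance test turns on.

penalty_j is the cost of a greedily assembled unit set meeting feature
j's target alone (units in decreasing r_ij/c_i order, ties by unit
index). It upper-bounds the cheapest single-feature cover, which is the
property a sufficiently large s_j needs in order to make meeting targets
worthwhile. The exact normalization Marxan applies internally is not
published; this form is a documented package choice, and numeric
reconciliation against Marxan binaries is out of scope.

## Exact route

The boundary term is linearized with one auxiliary y_ij per adjacent
pair: y_ij ≤ x_i, y_ij ≤ x_j, objective coefficient −2·b·v_ij. Because
the objective rewards y, every optimum has y_ij = min(x_i, x_j), so the
linear objective equals the quadratic form; y may be continuous in
[0, 1] without changing optima (smaller search tree than binary y). With
b = 0 no auxiliary variables are emitted.

Backend: HiGHS through `scipy.optimize.milp`, behind a small registry so
other MILP backends can be wired. Default gap tolerance is 0 — the point
of the exact route is a certified optimum. Unreachable targets are
rejected before solving; proven infeasibility raises; hitting a time
limit returns the incumbent with `optimal=False`, plus the certified
dual bound and residual gap in the solution provenance.

`brute_force` enumerates all 2^N selections (N ≤ 20) against the exact
quadratic objective and is the package's independent correctness oracle;
ties break toward the lexicographically smallest selection vector.
Equivalence tests compare objectives, never selection vectors, since the
MILP may return any optimum.

## Annealer

Marxan-style simulated annealing: single-unit flip proposals on the
penalized objective; improving moves always accepted, worsening moves
with probability exp(−Δ/T). Cooling is geometric over 100 blocks from an
initial temperature to a fraction 1e-4 of it. The initial temperature is
adaptive by default: the 0.9 quantile of |Δ| over 1,000 sampled flips
from a random start (floor 1e-6 for degenerate instances), so early
uphill moves are mostly accepted. Runs start from Bernoulli(0.5)
inclusion, track the best solution encountered, and finish with one
deterministic greedy removal sweep in unit-id order. Restart r of a
multi-restart run derives its seed from (master seed, r); proposal
units, acceptance uniforms and the temperature ladder are pre-generated
with numpy's Generator, so every run is bit-reproducible regardless of
the compiled kernel. Best-of-restarts selection prefers the cheapest
feasible run and falls back to the lowest penalized objective.

The inner loop is compiled with numba (~1–4 µs per proposal at desk
sizes); swap moves, thermal re-annealing and Marxan's clump/threshold
features are out of scope.

A structural note that the experiments surface repeatedly: with smooth
occupancy surfaces every unit holds a sliver of every feature, so the
penalized objective often has its optimum at an *epsilon-infeasible*
selection — dropping one unit leaves a tiny shortfall whose penalty is
below the unit's cost. Higher penalty factors shrink but do not abolish
the effect. This is a faithful property of the penalty form, not a bug;
summaries therefore always report feasibility alongside cost.

## Synthetic landscapes

The generator emulates the statistical shape of real inputs:

* **Autocorrelated fields** — white noise smoothed by a Gaussian kernel
  (sigma = `correlation_range`, in cells; reflective boundaries), then
  re-standardized. An explicit variogram model is deliberately not
  fitted; smoothing white noise is dependency-light, reproducible, and
  produces the smooth occupancy/cost maps that matter here.
* **Cost** — exp(mean_log + sigma_log·G): lognormal marginals, strictly
  positive and right-skewed like assessed land values. Defaults
  mean_log = 0, sigma_log = 1.
* **Occupancy** — logistic(steepness·(G_k − q_k)) per feature, with q_k
  solved by root-finding so the realized landscape mean equals the
  requested prevalence (default 0.25; steepness 2 gives a continuous
  gradient between strongholds and absences). Feature k draws a
  sub-seed from (seed, k), so extending the feature list never perturbs
  existing surfaces.
* **Aggregation** — planning units are factor×factor blocks of the fine
  raster: costs summed (total conserved to 1e-9 relative), occupancy
  averaged (stays in [0, 1]). Exact divisibility is required unless a
  trim option discards trailing cells. Rasters are row-major, 0-based,
  origin top-left.

What the generator does *not* emulate: detection/occupancy estimation
error, parcel geometry (all units are identical squares), correlated
cost–occupancy structure (cost and species fields are independent), and
inter-species dependence. Passing tests therefore demonstrate solver and
pipeline behaviour on realistically *shaped* inputs, not calibration to
any real region.

## Study conditions (desk scale)

The full-scale design — nine targets (10–90%) × five feature counts
(10–72) × three extents (9,282–148,510 units) = 135 exact scenarios,
×5 iteration counts ×4 penalty factors = 2,700 annealing scenarios, and
a 45-cell boundary sweep — is kept for scenario-grid arithmetic, but the
experiments run at desk scale, declared once in `minset.study`:

* extents 100 / 400 / 2,500 units (10×10, 20×20, 50×50; aggregated 2:1
  from a finer raster), feature counts 10 / 26 / 72, all nine targets;
* annealing iteration axis 1e3 / 1e4 / 1e5, SPF grid 1 / 5 / 25 / 125
  kept verbatim, best of 10 restarts;
* the cost sweep's annealer setting is the calibrated band: SPF 25,
  1e4 iterations, best-of-10;
* boundary sweep: 6×6 units, 6 features, b ∈ {0.1, 1, 10, 100, 1000};
* calibration experiment: 20 independent 100-unit, 6-feature landscapes
  at the 50% target.

Numerical choices:

* The cost sweep's exact solves use a 1% certification gap with a 60 s
  backstop. On these instances — dense, smooth, fractional coverage
  coefficients — proving the last few tenths of a percent costs minutes
  per instance while the incumbent stops improving almost immediately.
  Every dominance statement is therefore asserted against the solver's
  *certified dual bound*, which lower-bounds the true optimum at any
  gap; cost savings are reported against the incumbent. The
  oracle-equivalence, boundary-sweep and calibration studies keep
  gap 0.
* Objective comparisons use relative tolerance 1e-9 (1e-6 where a MILP
  incumbent is involved); shortfall feasibility uses the same relative
  tolerance against the target so floating accumulation cannot flag a
  met target as missed.
* Scenario s of a sweep derives its seed from (master seed, s); the
  whole result table is a pure function of the master seed (runtime
  column excluded).

## Known limitations

* The boundary penalty is the only connectivity mechanism; no
  locked-in/locked-out units, clump rules, or irreplaceability analysis.
* The annealer is a faithful algorithmic skeleton of Marxan's SA, not a
  bit-compatible clone; its absolute gaps should not be quoted as
  Marxan's.
* Exact-route runtimes grow quickly with extent at tight gaps on smooth
  synthetic inputs; the desk extents were chosen so every study runs on
  one CPU in minutes. Absolute cost figures from real cadastral or
  survey data are outside what synthetic landscapes can reproduce.
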