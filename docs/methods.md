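# Methods

This note records the modelling conventions, numerical choices and defaults
behind `hexsca`, and what the synthetic test conditions do and do not show.

## Grid geometry

Flat-top hexagons in odd-q offset indexing (odd columns shifted half a cell
down), 0-based. All geometry routes through cube coordinates, which makes
the six neighbour offsets, the hex metric ((|Δx|+|Δy|+|Δz|)/2) and straight
lines exact integer arithmetic. Centroids are scaled so adjacent centroids
are at unit distance in all six directions; cell area is taken as 1, so the
equal-area radius is √(N_a/π) in centroid units. Any consistent offset
convention yields the same dynamics; fixing one makes neighbour order,
RNG streams and therefore whole runs deterministic. Cells one step outside
the boundary are materialized as auxiliary cells: they join inclusion
sampling as empty cells, count in the H + K divisor, and absorb their share
(reported as `absorbed_mass`), which realizes the absorbing boundary and
the observed density deficit at boundary cells.

## Dispersion step conventions

Decisions where the formulation left room, and why:

- **Affectedness is exactly π > 0.** The update zeroes cells exactly, so 0
  is an attainable state; no epsilon threshold is used.
- **Neighbourhood grouping is metric**: affected cells are joined when
  pairwise hex distance ≤ 3 (at most two intervening cells on a shortest
  path), closed transitively. On a hex lattice a corridor-path reading of
  "separated by at most two empty cells" coincides on shortest paths.
- **d is the maximum absolute density difference** with the six
  neighbours. It must be nonnegative to be a probability factor; for an
  empty cell it reduces to the largest neighbouring density, so dispersal
  pressure from a dense neighbour raises inclusion, which is the intent.
- **Ties contribute**: a cell at exactly the included-cell mean is a
  contributor (π ≥ π̄), donating 0 and still receiving a share.
- **Survival is evaluated at the prospective density** (current density
  plus incoming share). For an occupied recipient this is ordinary
  density dependence; for a previously empty halo cell it makes the
  colonization odds depend on the size of the arriving cohort, which also
  reproduces the worked single-cell update exactly. Evaluation at the
  pre-update density is available via `ParamField(survival_at="current")`.
- **Failed survival zeroes the cell** by default; `retention` ∈ [0, 1)
  keeps that fraction of the pre-update density instead (the proportional
  -decrease generalization).
- **Mass ledger.** Per neighbourhood and step,
  Σπ(t+1) − Σπ(t) + (1−γ₂)π̃ + zeroed + absorbed = 0 exactly, where
  "zeroed" is the density destroyed by failed survival draws — the cell's
  prospective density (pre-update density plus its undelivered share).
  Boundedness of densities in [0, 1] follows from the update algebra
  without clipping and is asserted every step.
- **RNG streams** are keyed (seed, tag, t, anchor) with the anchor the
  smallest affected cell of a neighbourhood, so results are independent of
  neighbourhood processing order and a neighbourhood evolves identically
  whether simulated jointly with others or alone (the block-diagonal
  structure of the update). The microscale coupling uses one stream keyed
  (seed, tag, t) with replicates laid out over the sorted occupied cells:
  reproducible for a given seed, time and occupancy pattern.
- **Wind and barriers.** Barriers are boolean masks: masked cells are never
  affected, never halo, never receive. Wind is expressed through per-cell
  α/β rasters in the general inclusion probability (β < 1 raises p_I
  downwind, β > 1 suppresses it upwind); the `wind-field` fixture writes a
  simple two-level eastward raster.

## Parameters

| name | meaning | default | notes |
| --- | --- | --- | --- |
| γ₁ | fraction of above-mean density dispersed | 0.8 | base study setting |
| γ₂ | transit survival rate | 0.8 | 1 − γ₂ lost in transit |
| φ | baseline colonization probability | 1/3 | with ρ: φ + ρ·arctan ξ ≤ 1 |
| ρ | density-dependence of colonization | 1/3 | |
| α, β | inclusion emphasis exponents | 1 | per-cell rasters allowed |
| ξ | arctangent shape | 1 | |
| b, d | birth/death coefficients | 1, 0.2 | logistic births, linear deaths |
| C | carrying capacity per cell | 100 | |
| N | micro steps per macro step | 100 | validity: max (b_n+d_n)/N ≤ 1 |
| M | replicates per cell | 20 | replicate-mean couples back |

All scalar parameters may be per-cell rasters or callables of macro time.
X(0) = round(π·C) with ties to even. Cells at π = 0 run no microscale
dynamics (no immigration). The endemic/epidemic schedule presets (strong
birth only in a 4-step summer window of a 20-step year with elevated
winter death, versus birth above death year-round) are documented
approximations of seasonal forcing given only graphically in its sources.

## Statistics

The two complexity formulas are identical by construction (each internal
adjacency removes one boundary edge from each of the two cells) and are
cross-checked against an independent pairwise-adjacency oracle in the
tests. Run summaries for calibration: (1) time-averaged affected count,
(2) time-averaged mean density over affected cells (the all-cell average
would just rescale statistic 1), (3) time-averaged boundary complexity,
(4) least-squares slope of log-complexity versus time (the log fit is used
uniformly, also in regimes where raw complexity is nearly linear, for
consistency of the calibration observable). Neighbourhood identity over
time uses maximal-overlap matching of affected sets; a merge extends the
larger parent's series.

## Calibration

Only λ = (γ₁, φ) is calibrated: γ₂ is observationally confounded with φ
(both scale colonization success) and ρ has far weaker influence than φ,
so both stay fixed (γ₂ = 0.8, ρ = 1/3). The default box is γ₁ ∈ [0.4, 1.0]
and φ ∈ [1/6, 1 − ρπ/4 ≈ 0.738]; the upper φ bound is the admissibility
limit of the survival probability at ρ = 1/3. Every forward run starts
from a single affected cell of density 0.5 at the centre of a 30 × 30 grid
and lasts T = 30 macro steps; Q(λ) averages the chosen statistic over
R = 5 replicate runs by default. Observation noise for the noisy-data
model is diagonal and user-supplied. Densities on the observable space use
a Gaussian KDE with Silverman bandwidth up to 10³ points and a
Freedman–Diaconis histogram beyond; observations outside the pushforward
support (padded by half its range) are excluded with a warning. The
posterior is the uniform-ansatz importance-sampling solution: weights
∝ observed-density(Q)/pushforward-density(Q).

Desk-scale test conditions: synthetic observations use n = 100 draws from
the data-generating normal N((0.7, 1/3)ᵀ, 0.05²) with 10 replicate runs
each, and posteriors use 200 prior samples. These sizes keep a full
recovery experiment in minutes on one core while leaving the Monte-Carlo
error well inside the ±0.1 recovery tolerance for φ; production analyses
would raise all three by an order of magnitude.

## Test conditions and problem sizes

The suite exercises the model at the sizes a desk machine handles: grids
up to 50 × 50, runs up to 150 steps, ten-run averages for the complexity
decay law, and the calibration sizes above. The complexity-decay check
starts from a 7-cell compact seed (centre plus its six neighbours at
density 0.5): the reference regression for that law has intercept ≈ 0.71
(complexity ≈ 2), which identifies an initially compact pattern — a
single-cell start prepends a transient (complexity 6 → 2) that steepens
the fitted slope to ≈ −0.016 and does not belong to the decay law being
checked. The three limiting regimes are demonstrated with frozen
parameter triples found by a coarse scan: growth at the base settings,
fluctuation at (γ₁, γ₂, φ, ρ, b, d) = (0.5, 0.3, 0.12, 0.08, 1, 0.4), and
extinction at (0.8, 0.2, 0.05, 0.05, 0.3, 0.9).

## What the synthetic conditions do not show

The generator produces homogeneous landscapes with at most simple
barrier/wind structure; real forests add host heterogeneity, terrain and
weather covariance that the model's per-cell parameter fields can encode
but the tests do not exercise. Passing tests show internal consistency of
the update rules, statistics and calibration identities at these scales —
not that the parameter values fit any particular outbreak. The survey-image
pathway is tested against synthetic rasters round-tripped through the
documented conversion rules, not against a real aerial survey.

## Known limitations

- Dense pairwise distance matrices in neighbourhood grouping limit
  practical grids to ~10⁴ cells.
- The Δτ-discretized birth–death chain is first-order accurate in Δτ; no
  exact-event (Gillespie) path is provided.
- No geographic projection, variable cell sizes, rectangular-lattice mode,
  MCMC sampler, or calibration of the microscale rates.
- The cascaded multi-level variant (neighbourhoods as cells of a coarser
  automaton) is out of scope.
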