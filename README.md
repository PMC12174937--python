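# hexsca

A multiscale stochastic simulator of population dispersal on a hexagonal
grid, with pattern statistics and consistent-Bayes parameter calibration.
The model is motivated by outbreaks of the mountain pine beetle
(*Dendroctonus ponderosae*), whose infestations spread across forest
landscapes through short-range dispersal driven by tree-scale population
dynamics, but the machinery is generic: any density-based dispersal process
coupled to a per-site stochastic population model fits the framework.

It is intended for quantitative ecologists and modellers who want a small,
fully reproducible dispersal simulator whose parameters can be calibrated
from pattern summaries of survey imagery.

## The model

**Macroscale.** The landscape is an m × n grid of hexagonal cells holding
normalized densities π_ij(t) ∈ [0, 1]. Affected cells (π > 0) that are not
separated by more than two empty cells form *interaction neighbourhoods*,
which disperse independently. Within a neighbourhood, each cell (including
the unaffected halo) joins the step's dispersion with probability

    p_I = [ (w^α / (1 + w^α)) · d ]^β

where w counts adjacent affected cells (plus 1 for affected cells) and d is
the maximum density difference with the six neighbours. Included cells at
or above the included-cell mean π̄ donate γ₁(π − π̄) into a pool π̃, of
which the fraction γ₂ survives transit and is shared uniformly by the H + K
included cells. Non-contributing recipients keep their density plus the
share with probability

    p_S = φ + ρ · arctan(ξ π)        (φ + ρ · arctan ξ ≤ 1)

and are zeroed otherwise. Auxiliary cells beyond the boundary absorb their
share (absorbing boundary). Mass is accounted exactly: the density change
of the grid plus transit loss (1 − γ₂)π̃, zeroed density and absorbed
outflow sums to zero at machine precision every step.

**Microscale.** Each occupied cell hosts a birth–death chain on
{0, …, C} with logistic births b_n = n·b·(1 − n/C) and linear deaths
d_n = d·n, simulated with N steps of size Δτ = 1/N per macro step and
averaged over M replicates. The replicate-mean final count, divided by C,
becomes the cell's new density before each dispersion step (sequential
coupling). Optional periodic schedules modulate the rates to emulate
seasonal and endemic/epidemic forcing.

**Statistics and calibration.** Patterns are summarized by the affected
count, the mean affected density, the boundary complexity (boundary edges
per affected cell, identically (6N_a − Σn_a)/N_a), and the equal-area
radius about the density-weighted centre of mass. Calibration of
λ = (γ₁, φ) uses the stochastic-inverse-problem (consistent-Bayes)
formulation: uniform prior samples on Λ are re-weighted by the ratio of the
observed-data density to the prior pushforward density of the statistic
map Q(λ), so the posterior's pushforward through Q matches the observed
data distribution.

## Worked example

```python
import numpy as np
from hexsca import (DensityField, GridSpec, ParamField, BirthDeathSpec,
                    run_multiscale, calibration_statistics)

grid = GridSpec(30, 30)
v = np.zeros((30, 30)); v[15, 15] = 0.5          # one infested cell
params = ParamField(gamma1=0.8, gamma2=0.8, phi=1/3, rho=1/3)
bd = BirthDeathSpec(b=1.0, d=0.2, C=100, N=100, M=20)
snaps = run_multiscale(DensityField(v), params, grid, bd, steps=30, seed=1)
print((snaps[-1].values > 0).sum())               # affected cells at t=30
print(np.round(calibration_statistics(snaps, grid), 3))
```

prints

```
56
[21.258  0.425  2.945 -0.034]
```

— the infestation grew from 1 to 56 affected cells in 30 steps; averaged
over the run it covered 21.3 cells with mean density 0.425 and boundary
complexity 2.94, and the log-complexity declined at 0.034 per step (the
early transient from a single cell decays faster than the long-run rate of
about 0.01 seen over 150 steps).

The same run is available from the shell:

```sh
hexsca simulate --out run/ --seed 1
hexsca stats run/
```

## Layout

- `hexsca.hexgrid` — offset/cube hex geometry, Moore neighbourhoods, distances
- `hexsca.neighbourhoods` — interaction neighbourhoods and inclusion weights
- `hexsca.sca_core` — the dispersion step, parameters, mass accounting
- `hexsca.microscale` — birth–death chains, schedules, the coupling
- `hexsca.stats` — complexity, radius/centre-of-mass, rate series, run summaries
- `hexsca.calibration` — forward map, observation models, SIP posterior
- `hexsca.simulate` / `hexsca.cli` — run driver, config, fixtures, CLI

See `docs/methods.md` for the modelling choices, defaults and limitations.
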