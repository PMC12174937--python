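"""One macroscale dispersion step of the stochastic cellular automata.

Within each interaction neighbourhood, a step proceeds:

1. *Inclusion sampling.* Every member cell (affected + halo, auxiliary cells
   included) is included in dispersion with probability
   ``p_I = [(w^alpha / (1 + w^alpha)) * d]^beta`` (one Bernoulli draw per
   cell).  With ``alpha = beta = 1`` this is ``(w / (1 + w)) * d``.
2. *Partition.* Included cells with density at or above the included-cell
   mean ``pi_bar`` are *contributors*; the rest (including auxiliary cells)
   are *non-contributors*.  Contributors donate ``gamma1 * (pi - pi_bar)``
   into the dispersal pool ``pi_tilde``.
3. *Delivery.* Every included cell is offered the uniform share
   ``gamma2 * pi_tilde / (H + K)``; the fraction ``1 - gamma2`` of the pool
   is lost in transit.  Contributors always keep their share.  A
   non-contributor keeps its density plus the share only if its survival
   draw succeeds, with probability ``p_S = phi + rho * arctan(xi * pi)``;
   on failure the cell is zeroed (or scaled by an optional retention
   factor).  Auxiliary recipients absorb their share off-grid.

``p_S`` is evaluated at the cell's prospective post-receipt density
(current density + incoming share) by default, which reproduces the model's
single-cell worked update exactly and reduces to the plain rule for
occupied cells; evaluation at the pre-update density is available behind
``survival_at="current"``.

Dispersion in distinct neighbourhoods is independent; per-neighbourhood RNG
streams are derived from (seed, macro time, anchor cell), so processing a
neighbourhood on the full grid or alone on its own grid gives bit-identical
results.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

from .hexgrid import CellIndex, GridSpec
from .neighbourhoods import (
    DensityField,
    InclusionWeights,
    InteractionNeighbourhood,
    find_interaction_neighbourhoods,
    inclusion_weights,
)

__all__ = [
    "ParamField",
    "RandomDraws",
    "StepOutcome",
    "inclusion_probability",
    "survival_probability",
    "sample_inclusion",
    "partition_and_pool",
    "apply_dispersion",
    "macro_step",
    "transition_matrix",
]

_SURVIVAL_MODES = ("prospective", "current")


def _resolve(value, t):
    """Parameters may be scalars, (m, n) rasters, or callables of t."""
    return value(t) if callable(value) else value


def _at(value, cell: CellIndex, grid: GridSpec):
    if np.isscalar(value):
        return value
    arr = np.asarray(value)
    # auxiliary cells take the parameter of the nearest real cell
    i = min(max(cell.i, 0), grid.m - 1)
    j = min(max(cell.j, 0), grid.n - 1)
    return float(arr[i, j])


@dataclass
class ParamField:
    """Macroscale dispersion parameters.

    gamma1
        fraction of the above-mean density a contributor disperses, in [0, 1].
    gamma2
        dispersion survival rate: fraction of the pool that reaches hosts.
    phi, rho
        baseline and density-dependent parts of the survival probability
        ``p_S = phi + rho * arctan(xi * pi)``; requires
        ``phi + rho * arctan(xi) <= 1`` so ``p_S`` is a probability.
    alpha, beta
        emphasis exponents of the general inclusion probability (default 1).
    xi
        arctangent shape parameter (default 1).
    retention
        density fraction retained on a failed survival draw (default 0 =
        zeroing, the base model).
    survival_at
        density at which ``p_S`` is evaluated for non-contributors:
        "prospective" (current + incoming share; default) or "current".

    Each numeric parameter may be a scalar, an (m, n) per-cell raster, or a
    callable of macro time returning either.
    """

    gamma1: object = 0.8
    gamma2: object = 0.8
    phi: object = 1.0 / 3.0
    rho: object = 1.0 / 3.0
    alpha: object = 1.0
    beta: object = 1.0
    xi: object = 1.0
    retention: float = 0.0
    survival_at: str = "prospective"

    def __post_init__(self) -> None:
        if self.survival_at not in _SURVIVAL_MODES:
            raise ValueError(f"survival_at must be one of {_SURVIVAL_MODES}")
        for name in ("gamma1", "gamma2"):
            v = getattr(self, name)
            if not callable(v):
                a = np.asarray(v, dtype=float)
                if a.min() < 0 or a.max() > 1:
                    raise ValueError(f"{name} must lie in [0, 1]")
        for name in ("alpha", "beta", "xi"):
            v = getattr(self, name)
            if not callable(v) and np.min(np.asarray(v, dtype=float)) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not (0.0 <= self.retention < 1.0):
            raise ValueError("retention must lie in [0, 1)")
        if not any(callable(v) for v in (self.phi, self.rho, self.xi)):
            phi = np.asarray(self.phi, dtype=float)
            rho = np.asarray(self.rho, dtype=float)
            xi = np.asarray(self.xi, dtype=float)
            if np.min(phi) < 0 or np.min(rho) < 0:
                raise ValueError("phi and rho must be nonnegative")
            bound = phi + rho * np.arctan(xi)
            if np.max(bound) > 1.0 + 1e-12:
                raise ValueError(
                    "survival probability constraint violated: "
                    "phi + rho*arctan(xi) must be <= 1"
                )


@dataclass
class RandomDraws:
    """Realized Bernoulli draws for one neighbourhood and step."""

    inclusion: Dict[CellIndex, int]
    survival: Optional[Dict[CellIndex, int]] = None
    seed: Optional[int] = None


@dataclass
class StepOutcome:
    """Per-neighbourhood accounting of one dispersion step.

    The mass ledger balances to machine precision:
    ``sum(pi(t+1)) - sum(pi(t)) + lost_in_transit + zeroed_mass +
    absorbed_mass == 0`` where ``zeroed_mass`` is the density (pre-update
    density plus undelivered share) destroyed by failed survival draws.
    """

    nbhd_id: int
    included: Set[CellIndex] = dc_field(default_factory=set)
    contributors: Set[CellIndex] = dc_field(default_factory=set)
    noncontributors: Set[CellIndex] = dc_field(default_factory=set)
    pool: float = 0.0
    mean_density: float = 0.0
    zeroed: Set[CellIndex] = dc_field(default_factory=set)
    zeroed_mass: float = 0.0
    absorbed_mass: float = 0.0
    lost_in_transit: float = 0.0
    next_field: Optional[DensityField] = None


def inclusion_probability(w, d, alpha=1.0, beta=1.0):
    """General inclusion probability ``[(w^a / (1 + w^a)) * d]^b``.

    Accepts scalars or arrays; returns 0 where ``w == 0``.
    """
    if np.min(alpha) <= 0 or np.min(beta) <= 0:
        raise ValueError("alpha and beta must be strictly positive")
    w = np.asarray(w, dtype=float)
    d = np.asarray(d, dtype=float)
    wa = w**alpha
    p = ((wa / (1.0 + wa)) * d) ** beta
    return float(p) if p.ndim == 0 else p


def survival_probability(pi, phi, rho, xi=1.0):
    """Dispersion survival probability ``phi + rho * arctan(xi * pi)``."""
    p = phi + rho * np.arctan(xi * np.asarray(pi, dtype=float))
    return float(p) if np.ndim(p) == 0 else p


def sample_inclusion(
    nbhd: InteractionNeighbourhood,
    weights: InclusionWeights,
    params: ParamField,
    rng,
    grid: GridSpec,
    t: int = 0,
) -> RandomDraws:
    """One Bernoulli(p_I) draw per member cell, in sorted cell order."""
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    alpha = _resolve(params.alpha, t)
    beta = _resolve(params.beta, t)
    draws: Dict[CellIndex, int] = {}
    for cell in sorted(nbhd.members):
        p = inclusion_probability(
            weights.w[cell], weights.d[cell], _at(alpha, cell, grid), _at(beta, cell, grid)
        )
        draws[cell] = int(rng.random() < p)
    return RandomDraws(inclusion=draws)


def partition_and_pool(
    densities: Dict[CellIndex, float], gamma1, grid: Optional[GridSpec] = None
):
    """Split included cells into contributors/non-contributors; build the pool.

    ``densities`` maps each included cell to its current density (auxiliary
    cells carry 0).  Returns ``(pi_bar, contributors, noncontributors,
    pi_tilde)`` or ``None`` when no cell is included (the neighbourhood is
    skipped this step).  Contributors are real cells with ``pi >= pi_bar``;
    auxiliary cells are always non-contributing sinks.
    """
    if not densities:
        return None
    vals = np.array(list(densities.values()), dtype=float)
    pi_bar = float(vals.mean())
    contributors = set()
    noncontributors = set()
    pool = 0.0
    for cell, pi in densities.items():
        if not cell.is_auxiliary and pi >= pi_bar:
            contributors.add(cell)
            g1 = _at(gamma1, cell, grid) if grid is not None else gamma1
            pool += g1 * (pi - pi_bar)
        else:
            noncontributors.add(cell)
    return pi_bar, contributors, noncontributors, pool


def _disperse_into(
    out: np.ndarray,
    nbhd: InteractionNeighbourhood,
    draws: RandomDraws,
    params: ParamField,
    values: np.ndarray,
    grid: GridSpec,
    t: int,
    rng,
) -> StepOutcome:
    """Apply one neighbourhood's dispersion update, writing into ``out``."""
    outcome = StepOutcome(nbhd_id=nbhd.id)
    included = {c for c, b in draws.inclusion.items() if b}
    missing = nbhd.members - set(draws.inclusion)
    if missing:
        raise ValueError(f"inclusion draws missing for cells: {sorted(missing)[:3]}")
    if not included:
        return outcome

    densities = {
        c: (0.0 if c.is_auxiliary else float(values[c.i, c.j])) for c in included
    }
    gamma1 = _resolve(params.gamma1, t)
    gamma2 = _resolve(params.gamma2, t)
    phi = _resolve(params.phi, t)
    rho = _resolve(params.rho, t)
    xi = _resolve(params.xi, t)

    pi_bar, contributors, noncontributors, pool = partition_and_pool(
        densities, gamma1, grid
    )
    hk = len(included)
    outcome.included = included
    outcome.contributors = contributors
    outcome.noncontributors = noncontributors
    outcome.mean_density = pi_bar
    outcome.pool = pool

    base_share = pool / hk  # pre-survival-rate share per included cell
    lost = 0.0

    for cell in contributors:
        share = _at(gamma2, cell, grid) * base_share
        lost += base_share - share
        pi = densities[cell]
        out[cell.i, cell.j] = pi - _at(gamma1, cell, grid) * (pi - pi_bar) + share

    survival = draws.survival
    need_draw = survival is None
    for cell in sorted(noncontributors):
        share = _at(gamma2, cell, grid) * base_share
        lost += base_share - share
        if cell.is_auxiliary:
            outcome.absorbed_mass += share
            continue
        pi = densities[cell]
        if need_draw:
            level = pi + share if params.survival_at == "prospective" else pi
            p_s = survival_probability(
                level, _at(phi, cell, grid), _at(rho, cell, grid), _at(xi, cell, grid)
            )
            b_s = int(rng.random() < p_s)
        else:
            if cell not in survival:
                raise ValueError(f"survival draw missing for cell {cell}")
            b_s = int(survival[cell])
        if b_s:
            out[cell.i, cell.j] = pi + share
        else:
            kept = params.retention * pi
            out[cell.i, cell.j] = kept
            outcome.zeroed.add(cell)
            outcome.zeroed_mass += pi + share - kept

    outcome.lost_in_transit = lost
    return outcome


def apply_dispersion(
    nbhd: InteractionNeighbourhood,
    draws: RandomDraws,
    params: ParamField,
    field: DensityField,
    grid: GridSpec,
    rng=None,
    t: Optional[int] = None,
) -> StepOutcome:
    """Apply one neighbourhood's update and return the full next field.

    If ``draws.survival`` is None, survival draws are taken from ``rng``
    (in sorted non-contributor order); otherwise the forced draws are used.
    """
    if t is None:
        t = field.time
    if draws.survival is None and rng is None:
        rng = np.random.default_rng(0 if draws.seed is None else draws.seed)
    out = field.values.copy()
    outcome = _disperse_into(out, nbhd, draws, params, field.values, grid, t, rng)
    outcome.next_field = DensityField(out, time=t + 1)
    return outcome


def _nbhd_rng(seed: int, t: int, anchor: CellIndex):
    # tag 1 = macroscale streams; the microscale coupling uses tag 2
    return np.random.default_rng((int(seed), 1, int(t), int(anchor.i), int(anchor.j)))


def macro_step(
    field: DensityField,
    params: ParamField,
    grid: GridSpec,
    seed: int,
    barrier: Optional[np.ndarray] = None,
    t: Optional[int] = None,
) -> Tuple[DensityField, List[StepOutcome]]:
    """One full macroscale dispersion step over all neighbourhoods.

    Neighbourhood RNG streams are keyed on (seed, t, anchor cell), so the
    result is independent of processing order and identical whether a
    neighbourhood is simulated jointly with others or alone.
    """
    if t is None:
        t = field.time
    values = field.values
    if barrier is not None:
        barrier = np.asarray(barrier, dtype=bool)
        if np.any(values[barrier] > 0):
            values = values.copy()
            values[barrier] = 0.0
    nbhds = find_interaction_neighbourhoods(
        DensityField(values, field.time), grid, barrier
    )
    out = values.copy()
    outcomes: List[StepOutcome] = []
    for nbhd in nbhds:
        rng = _nbhd_rng(seed, t, nbhd.anchor)
        weights = inclusion_weights(nbhd, DensityField(values, field.time), grid)
        draws = sample_inclusion(nbhd, weights, params, rng, grid, t)
        outcomes.append(
            _disperse_into(out, nbhd, draws, params, values, grid, t, rng)
        )
    return DensityField(out, time=t + 1), outcomes


def transition_matrix(
    nbhd: InteractionNeighbourhood,
    draws: RandomDraws,
    params: ParamField,
    field: DensityField,
    grid: GridSpec,
    t: int = 0,
) -> Tuple[np.ndarray, List[CellIndex]]:
    """Assemble the realized update as a matrix over the neighbourhood cells.

    Given the sampled draws, the update is linear in the state: the mean
    ``pi_bar``, pool and shares are all linear functionals of the member
    densities.  Returns ``(T, cells)`` with real member cells in sorted
    order such that ``T @ state == next state`` exactly.  Requires forced
    survival draws (the matrix is only defined once all draws are fixed).
    """
    if draws.survival is None:
        raise ValueError("transition_matrix requires explicit survival draws")
    cells = sorted(c for c in nbhd.members if not c.is_auxiliary)
    idx = {c: k for k, c in enumerate(cells)}
    nreal = len(cells)
    gamma1 = _resolve(params.gamma1, t)
    gamma2 = _resolve(params.gamma2, t)

    included = [c for c in cells if draws.inclusion.get(c)]
    n_aux_inc = sum(
        1 for c in nbhd.members if c.is_auxiliary and draws.inclusion.get(c)
    )
    hk = len(included) + n_aux_inc
    T = np.eye(nreal)
    if hk == 0:
        return T, cells

    values = field.values
    u = np.zeros(nreal)
    for c in included:
        u[idx[c]] = 1.0
    pi_bar_vec = u / hk  # aux cells contribute 0 density to the mean
    dens = {c: float(values[c.i, c.j]) for c in included}
    pi_bar = sum(dens.values()) / hk
    contrib = [c for c in included if dens[c] >= pi_bar]
    H = len(contrib)
    cvec = np.zeros(nreal)
    for c in contrib:
        cvec[idx[c]] = _at(gamma1, c, grid)
    # pool row: sum_h gamma1_h * (x_h - pi_bar)
    pool_vec = cvec - (cvec.sum()) * pi_bar_vec if H else np.zeros(nreal)
    # note: with per-cell gamma1 the mean term uses sum of contributors' gamma1
    for c in cells:
        k = idx[c]
        if c not in dens:
            continue  # not included: identity row
        share_vec = _at(gamma2, c, grid) / hk * pool_vec
        if c in contrib:
            g1 = _at(gamma1, c, grid)
            row = np.zeros(nreal)
            row[k] = 1.0 - g1
            row += g1 * pi_bar_vec + share_vec
        elif draws.survival.get(c):
            row = np.zeros(nreal)
            row[k] = 1.0
            row += share_vec
        else:
            row = np.zeros(nreal)
            row[k] = params.retention
        T[k] = row
    return T, cells
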