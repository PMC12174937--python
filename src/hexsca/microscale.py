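"""Microscale stochastic birth--death population dynamics and coupling.

Each cell hosts a discrete-state birth--death chain on {0, ..., C} with a
logistic birth rate ``b_n = n * b * (1 - n/C)`` and a linear death rate
``d_n = d * n``, simulated by its Delta-tau discretization (Delta-tau =
1/N): per micro step the population moves up with probability
``b_n * Delta-tau``, down with probability ``d_n * Delta-tau``, else stays.
State 0 is absorbing (no immigration), and ``b_C = 0`` keeps the chain in
range, so no clamping is needed.  Validity requires
``max_n (b_n + d_n) * Delta-tau <= 1``.

Optional multiplicative schedules modulate the rates with macro time to
emulate seasonal forcing: a sinusoidal birth factor ``1 + sin(2*pi*t/T)``
(the annual cycle with a T-step year) and endemic/epidemic presets.

The sequential coupling converts each macro density to a population
``X(0) = round(pi * C)`` (ties to even), runs M independent replicates for
N micro steps, and maps the replicate-mean final count back to a density.
Cells with zero density stay empty (the model has no immigration).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional, Tuple

import numpy as np

from .neighbourhoods import DensityField

__all__ = [
    "BirthDeathSpec",
    "bd_rates",
    "bd_step",
    "simulate_trajectory",
    "couple_microscale",
    "sinusoidal_schedule",
    "endemic_schedules",
    "epidemic_schedules",
]


def sinusoidal_schedule(period: float) -> Callable[[float], float]:
    """Annual-cycle modulation factor ``1 + sin(2*pi*t/period)``."""

    def factor(t: float) -> float:
        return 1.0 + math.sin(2.0 * math.pi * t / period)

    return factor


def endemic_schedules(year: int = 20) -> Tuple[Callable, Callable]:
    """Endemic-regime rate modulations over a ``year``-step year.

    Birth is strong only during a short summer window; death exceeds birth
    through the cold remainder of the year, so the population barely holds
    on.  The shapes are documented approximations of seasonal forcing.
    """
    summer = range(2 * year // 5, 3 * year // 5)

    def birth(t: float) -> float:
        return 2.0 if int(t) % year in summer else 0.2

    def death(t: float) -> float:
        return 0.3 if int(t) % year in summer else 1.5

    return birth, death


def epidemic_schedules(year: int = 20) -> Tuple[Callable, Callable]:
    """Epidemic-regime modulations: birth exceeds death all year."""

    def birth(t: float) -> float:
        return 1.5

    def death(t: float) -> float:
        return 0.5

    return birth, death


@dataclass
class BirthDeathSpec:
    """Birth--death model: rates, capacity, micro resolution, replicates."""

    b: float = 1.0
    d: float = 0.2
    C: int = 100
    N: int = 100
    M: int = 20
    birth_schedule: Optional[Callable[[float], float]] = None
    death_schedule: Optional[Callable[[float], float]] = None

    def __post_init__(self) -> None:
        if self.b < 0 or self.d < 0:
            raise ValueError("rate coefficients must be nonnegative")
        if self.C < 1 or self.N < 1 or self.M < 1:
            raise ValueError("C, N and M must be positive integers")
        self._check_validity(t=0, factors=(1.0, 1.0))

    def _check_validity(self, t: float, factors=None) -> None:
        fb, fd = factors if factors is not None else (
            self.birth_schedule(t) if self.birth_schedule else 1.0,
            self.death_schedule(t) if self.death_schedule else 1.0,
        )
        # max of logistic birth rate is b*C/4 at n = C/2; death max is d*C
        worst = (fb * self.b * self.C / 4.0 + fd * self.d * self.C) / self.N
        if worst > 1.0 + 1e-12:
            raise ValueError(
                f"(b_n + d_n) * Dtau exceeds 1 (={worst:.3f}); increase N "
                "or reduce the rates"
            )


def bd_rates(n, t: float, spec: BirthDeathSpec):
    """Instantaneous rates ``(b_n, d_n)`` at population ``n``, macro time t."""
    n_arr = np.asarray(n, dtype=float)
    if np.min(n_arr) < 0 or np.max(n_arr) > spec.C:
        raise IndexError(f"population must lie in 0..{spec.C}")
    fb = spec.birth_schedule(t) if spec.birth_schedule else 1.0
    fd = spec.death_schedule(t) if spec.death_schedule else 1.0
    b_n = n_arr * spec.b * (1.0 - n_arr / spec.C) * fb
    d_n = spec.d * n_arr * fd
    if np.ndim(n) == 0:
        return float(b_n), float(d_n)
    return b_n, d_n


def bd_step(n, t: float, spec: BirthDeathSpec, rng):
    """One micro step of the discretized chain (scalar or array state)."""
    spec._check_validity(t)
    b_n, d_n = bd_rates(n, t, spec)
    p_up = np.asarray(b_n) / spec.N
    p_down = np.asarray(d_n) / spec.N
    u = rng.random(np.shape(n)) if np.ndim(n) else rng.random()
    step = np.where(u < p_up, 1, np.where(u < p_up + p_down, -1, 0))
    result = np.asarray(n) + step
    return int(result) if np.ndim(n) == 0 else result


def simulate_trajectory(n0: int, spec: BirthDeathSpec, rng, t: float = 0.0):
    """A full trajectory X_0..X_N over one macro step (for diagnostics)."""
    counts = np.empty(spec.N + 1, dtype=int)
    counts[0] = n0
    n = n0
    for k in range(spec.N):
        n = bd_step(n, t, spec, rng)
        counts[k + 1] = n
    return counts


def couple_microscale(
    field: DensityField, spec: BirthDeathSpec, t: float, seed_or_rng
) -> DensityField:
    """Advance every occupied cell through M replicate micro simulations.

    Replicates for all occupied cells evolve in one vectorized block of
    shape (cells, M); the RNG stream is keyed (seed, 2, t) with cells in
    sorted order, so the update is reproducible for a given seed, time and
    occupancy pattern.
    """
    if isinstance(seed_or_rng, (int, np.integer)):
        rng = np.random.default_rng((int(seed_or_rng), 2, int(t)))
    else:
        rng = seed_or_rng
    spec._check_validity(t)
    values = field.values
    ii, jj = np.nonzero(values > 0)
    if ii.size == 0:
        return field.copy()
    order = np.lexsort((jj, ii))
    ii, jj = ii[order], jj[order]
    x0 = np.round(values[ii, jj] * spec.C)  # numpy rounds ties to even
    counts = np.broadcast_to(x0[:, None], (ii.size, spec.M)).astype(float).copy()

    fb = spec.birth_schedule(t) if spec.birth_schedule else 1.0
    fd = spec.death_schedule(t) if spec.death_schedule else 1.0
    bN = spec.b * fb / spec.N
    dN = spec.d * fd / spec.N
    for _ in range(spec.N):
        p_up = counts * bN * (1.0 - counts / spec.C)
        p_down = counts * dN
        u = rng.random(counts.shape)
        counts += np.where(u < p_up, 1.0, 0.0) - np.where(
            (u >= p_up) & (u < p_up + p_down), 1.0, 0.0
        )
    out = values.copy()
    out[ii, jj] = counts.mean(axis=1) / spec.C
    return DensityField(out, time=field.time)
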