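"""Consistent-Bayes (stochastic inverse problem) calibration of (gamma1, phi).

The observable map ``Q(lambda)`` is the expected value of a chosen pattern
statistic of the dispersion model at parameter value ``lambda = (gamma1,
phi)``, estimated by averaging over R replicate multiscale runs from a
standard initial pattern.  Given observed data {q_i}, the SIP posterior
with the non-informative *uniform ansatz* prior re-weights uniform prior
samples by the ratio of the observed-data density to the prior pushforward
density evaluated at ``Q(lambda)`` — a form of importance sampling whose
posterior pushforward matches the observed-data distribution.

The remaining parameters are held fixed (gamma2 and rho in particular,
because their effect on the statistics is nearly indistinguishable from
phi's, making them jointly unidentifiable from pattern data).

Densities on the observable space use a Gaussian kernel estimate
(Silverman bandwidth) up to 1000 points and a Freedman--Diaconis histogram
beyond that.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np
from scipy.stats import gaussian_kde

from .hexgrid import GridSpec, moore_neighbors
from .microscale import BirthDeathSpec
from .neighbourhoods import DensityField
from .sca_core import ParamField
from .simulate import run_multiscale
from .stats import calibration_statistics

__all__ = [
    "CalibrationProblem",
    "ObservationSet",
    "Posterior",
    "forward_map",
    "generate_synthetic_observations",
    "image_to_density",
    "sip_posterior",
    "posterior_summaries",
]


@dataclass
class CalibrationProblem:
    """Domain, fixed parameters and forward-model settings for the SIP.

    The default box is gamma1 in [0.4, 1.0] and phi in [1/6, 1 - rho*pi/4]
    (the admissible survival-probability range); gamma2 = 0.8 and rho = 1/3
    stay fixed.  Every forward run starts from a single affected cell of density
    0.5 at the centre of a 30x30 grid and lasts T = 30 macro steps;
    ``statistic`` selects which of the four run summaries (1-based) is the
    observable.
    """

    gamma1_bounds: Tuple[float, float] = (0.4, 1.0)
    # phi upper default is the admissible limit 1 - rho*pi/4 for rho = 1/3
    phi_bounds: Tuple[float, float] = (1.0 / 6.0, 1.0 - np.pi / 12.0)
    gamma2: float = 0.8
    rho: float = 1.0 / 3.0
    bd: BirthDeathSpec = dc_field(default_factory=BirthDeathSpec)
    T: int = 30
    R: int = 5
    statistic: int = 1
    m: int = 30
    n: int = 30
    initial_density: float = 0.5

    def __post_init__(self) -> None:
        if not 1 <= self.statistic <= 4:
            raise ValueError("statistic must be 1..4")
        if self.R < 1:
            raise ValueError("R must be >= 1")
        phi_max = 1.0 - self.rho * np.pi / 4.0
        if self.phi_bounds[1] > phi_max + 1e-12:
            raise ValueError(
                f"phi upper bound {self.phi_bounds[1]} exceeds admissible "
                f"{phi_max:.4f} for rho={self.rho}"
            )

    def grid(self) -> GridSpec:
        return GridSpec(self.m, self.n)

    def in_domain(self, lam) -> bool:
        g1, phi = lam
        return (
            self.gamma1_bounds[0] <= g1 <= self.gamma1_bounds[1]
            and self.phi_bounds[0] <= phi <= self.phi_bounds[1]
        )

    def params(self, lam) -> ParamField:
        g1, phi = lam
        return ParamField(gamma1=g1, gamma2=self.gamma2, phi=phi, rho=self.rho)

    def initial_field(self) -> DensityField:
        values = np.zeros((self.m, self.n))
        values[self.m // 2, self.n // 2] = self.initial_density
        return DensityField(values)


@dataclass
class ObservationSet:
    """Observed statistic values and how they were generated."""

    data: np.ndarray
    generator: str = "synthetic"
    lambdas: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.data = np.atleast_1d(np.asarray(self.data, dtype=float))
        if self.data.size == 0:
            raise ValueError("observation set must be non-empty")


@dataclass
class Posterior:
    """Weighted parameter sample approximating the SIP posterior."""

    samples: np.ndarray  # (n, 2) columns (gamma1, phi)
    weights: np.ndarray
    q_values: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if np.any(w < 0):
            raise ValueError("weights must be nonnegative")
        total = w.sum()
        if total <= 0:
            raise ValueError("degenerate posterior: all weights are zero")
        self.weights = w / total

    def mean(self) -> np.ndarray:
        return self.weights @ self.samples


def _run_statistic(problem: CalibrationProblem, params, seed: int) -> float:
    snapshots = run_multiscale(
        problem.initial_field(), params, problem.grid(), problem.bd, problem.T, seed
    )
    return float(calibration_statistics(snapshots, problem.grid())[problem.statistic - 1])


def forward_map(lam, problem: CalibrationProblem, seed: int, reps: Optional[int] = None) -> float:
    """Mean of the chosen statistic over ``reps`` (default R) replicate runs."""
    if not problem.in_domain(lam):
        raise ValueError(f"lambda {lam} outside the calibration domain")
    reps = problem.R if reps is None else reps
    params = problem.params(lam)
    ss = np.random.SeedSequence(int(seed) & 0x7FFFFFFF)
    run_seeds = ss.generate_state(reps)
    vals = []
    for r in range(reps):
        # runs with no surviving pattern carry no statistic; treat a fully
        # extinct run as contributing its defined parts where possible
        try:
            vals.append(_run_statistic(problem, params, int(run_seeds[r]) & 0x7FFFFFFF))
        except ValueError:
            vals.append(0.0 if problem.statistic in (1, 2) else np.nan)
    arr = np.asarray(vals, dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size == 0:
        raise ValueError("all replicate runs died out before the statistic existed")
    return float(arr.mean())


def generate_synthetic_observations(
    problem: CalibrationProblem,
    n: int,
    reps: int,
    seed: int,
    mean: Tuple[float, float] = (0.7, 1.0 / 3.0),
    sd: float = 0.05,
) -> ObservationSet:
    """Draw lambda_i from a truncated normal data-generating distribution
    and record the replicate-averaged statistic for each."""
    rng = np.random.default_rng((int(seed), 3))
    lambdas = np.empty((n, 2))
    for k in range(n):
        while True:
            lam = rng.normal(mean, sd)
            if problem.in_domain(lam):
                lambdas[k] = lam
                break
    obs_seeds = rng.integers(0, 2**31 - 1, size=n)
    data = np.array(
        [
            forward_map(lambdas[k], problem, int(obs_seeds[k]), reps=reps)
            for k in range(n)
        ]
    )
    return ObservationSet(data=data, generator="synthetic", lambdas=lambdas)


def image_to_density(
    image,
    target: Tuple[int, int] = (32, 32),
    threshold: float = 0.8,
    noise_sd_nonzero: float = 0.2,
    noise_sd_adjacent: float = 0.6,
    seed: Optional[int] = None,
    grid: Optional[GridSpec] = None,
) -> DensityField:
    """Convert a grayscale raster into a noisy density field.

    Grey levels are divided by 256; entries below ``threshold`` are zeroed;
    Gaussian noise of sd ``noise_sd_nonzero`` is added to non-zero cells
    and sd ``noise_sd_adjacent`` to zero cells adjacent (hex Moore
    neighbourhood) to at least one non-zero cell; the result is clamped to
    [0, 1].  Pass ``seed=None`` for the noiseless conversion.
    """
    from PIL import Image

    if isinstance(image, np.ndarray):
        arr = image.astype(float)
        if target is not None and arr.shape != tuple(target):
            img = Image.fromarray(arr.astype(np.uint8), mode="L")
            arr = np.asarray(img.resize(target[::-1], Image.BILINEAR), dtype=float)
    else:
        img = Image.open(image).convert("L")
        if target is not None:
            img = img.resize(target[::-1], Image.BILINEAR)
        arr = np.asarray(img, dtype=float)

    dens = arr / 256.0
    dens[dens < threshold] = 0.0
    if seed is not None:
        rng = np.random.default_rng(seed)
        g = grid or GridSpec(*dens.shape)
        nonzero = dens > 0
        adjacent = np.zeros_like(nonzero)
        ii, jj = np.nonzero(nonzero)
        for a, b in zip(ii, jj):
            for nb in moore_neighbors(g.cell(int(a), int(b)), g):
                if not nb.is_auxiliary and not nonzero[nb.i, nb.j]:
                    adjacent[nb.i, nb.j] = True
        dens = dens.copy()
        dens[nonzero] += rng.normal(0.0, noise_sd_nonzero, int(nonzero.sum()))
        dens[adjacent] += rng.normal(0.0, noise_sd_adjacent, int(adjacent.sum()))
        dens = np.clip(dens, 0.0, 1.0)
    return DensityField(np.clip(dens, 0.0, 1.0))


def _density_estimator(samples: np.ndarray) -> Callable[[np.ndarray], np.ndarray]:
    samples = np.asarray(samples, dtype=float)
    if samples.size <= 1000:
        if np.ptp(samples) < 1e-12:
            # degenerate sample: a narrow Gaussian bump at the common value
            centre, width = samples.mean(), max(1e-3, abs(samples.mean()) * 0.01)

            def pdf(x):
                x = np.asarray(x, dtype=float)
                return np.exp(-0.5 * ((x - centre) / width) ** 2) / (
                    width * np.sqrt(2 * np.pi)
                )

            return pdf
        kde = gaussian_kde(samples, bw_method="silverman")
        return lambda x: kde(np.atleast_1d(x))
    counts, edges = np.histogram(samples, bins="fd", density=True)

    def pdf(x):
        x = np.atleast_1d(np.asarray(x, dtype=float))
        k = np.clip(np.searchsorted(edges, x, side="right") - 1, 0, len(counts) - 1)
        out = counts[k]
        out[(x < edges[0]) | (x > edges[-1])] = 0.0
        return out

    return pdf


def sip_posterior(
    problem: CalibrationProblem,
    observations: ObservationSet,
    n_prior: int,
    seed: int,
    observed_density: Optional[Callable] = None,
    q_values: Optional[np.ndarray] = None,
    samples: Optional[np.ndarray] = None,
) -> Posterior:
    """Uniform-ansatz SIP posterior by pushforward re-weighting.

    Draws ``n_prior`` uniform prior samples on the box, evaluates Q at
    each, estimates the prior pushforward density and the observed-data
    density on the observable space, and weights each prior sample by
    ``observed(Q) / pushforward(Q)``.  Observations outside the support of
    the pushforward estimate are flagged and excluded.  ``q_values`` and
    ``samples`` allow re-use of precomputed forward evaluations.
    """
    if n_prior < 100:
        raise ValueError("n_prior must be at least 100")
    rng = np.random.default_rng((int(seed), 4))
    if samples is None:
        lo = np.array([problem.gamma1_bounds[0], problem.phi_bounds[0]])
        hi = np.array([problem.gamma1_bounds[1], problem.phi_bounds[1]])
        samples = rng.uniform(lo, hi, size=(n_prior, 2))
    else:
        samples = np.asarray(samples, dtype=float)
    if q_values is None:
        fwd_seeds = rng.integers(0, 2**31 - 1, size=len(samples))
        q_values = np.array(
            [
                forward_map(samples[k], problem, int(fwd_seeds[k]))
                for k in range(len(samples))
            ]
        )
    else:
        q_values = np.asarray(q_values, dtype=float)

    push_pdf = _density_estimator(q_values)
    if observed_density is None:
        obs = observations.data
        support = (q_values.min(), q_values.max())
        pad = 0.5 * (support[1] - support[0]) + 1e-12
        ok = (obs >= support[0] - pad) & (obs <= support[1] + pad)
        if not ok.all():
            warnings.warn(
                f"{int((~ok).sum())} observation(s) outside the pushforward "
                "support were excluded"
            )
            obs = obs[ok]
        if obs.size == 0:
            raise ValueError("no observation lies in the pushforward support")
        observed_density = _density_estimator(obs)

    push_at_q = np.maximum(push_pdf(q_values), 1e-300)
    weights = observed_density(q_values) / push_at_q
    return Posterior(samples=samples, weights=weights, q_values=q_values)


@dataclass
class PosteriorSummaries:
    mean: np.ndarray
    marginal_grids: Tuple[np.ndarray, np.ndarray]  # evaluation points per axis
    marginals: Tuple[np.ndarray, np.ndarray]  # weighted KDE values per axis
    joint_grid: np.ndarray  # (g, g) joint density over the box


def posterior_summaries(
    posterior: Posterior,
    problem: Optional[CalibrationProblem] = None,
    grid_points: int = 60,
) -> PosteriorSummaries:
    """Weighted marginal densities, joint density grid and posterior mean."""
    s, w = posterior.samples, posterior.weights
    if problem is not None:
        bounds = (problem.gamma1_bounds, problem.phi_bounds)
    else:
        bounds = tuple((s[:, k].min(), s[:, k].max()) for k in range(2))
    axes = tuple(
        np.linspace(bounds[k][0], bounds[k][1], grid_points) for k in range(2)
    )
    marginals = []
    for k in range(2):
        if np.ptp(s[:, k]) < 1e-12:
            dens = np.zeros(grid_points)
            dens[np.argmin(np.abs(axes[k] - s[0, k]))] = 1.0
        else:
            kde = gaussian_kde(s[:, k], weights=w, bw_method="silverman")
            dens = kde(axes[k])
        marginals.append(dens)
    if np.ptp(s[:, 0]) < 1e-12 or np.ptp(s[:, 1]) < 1e-12:
        joint = np.outer(marginals[0], marginals[1])
    else:
        kde2 = gaussian_kde(s.T, weights=w, bw_method="silverman")
        gx, gy = np.meshgrid(axes[0], axes[1], indexing="ij")
        joint = kde2(np.vstack([gx.ravel(), gy.ravel()])).reshape(gx.shape)
    return PosteriorSummaries(
        mean=posterior.mean(),
        marginal_grids=axes,
        marginals=tuple(marginals),
        joint_grid=joint,
    )
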