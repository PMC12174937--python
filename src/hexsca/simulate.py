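"""Simulation driver, configuration, serialization and fixture generation.

A run alternates the microscale coupling and one macroscale dispersion
step: at macro time ``t - 1`` the birth--death replicates update every
occupied cell's density, then the SCA disperses the result to time ``t``.
Snapshots are written as plain delimited-text matrices (row-major m x n)
for diffability, statistics as a tidy CSV table, and the manifest as YAML;
an identical manifest reproduces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .hexgrid import GridSpec, hex_distance
from .microscale import (
    BirthDeathSpec,
    couple_microscale,
    endemic_schedules,
    epidemic_schedules,
    sinusoidal_schedule,
)
from .neighbourhoods import DensityField, find_interaction_neighbourhoods
from .sca_core import ParamField, macro_step
from .stats import pattern_summary

__all__ = [
    "RunConfig",
    "run_multiscale",
    "run_simulation",
    "make_fixture",
    "read_density",
    "write_density",
]

_SCHEDULES = ("none", "sinusoidal", "endemic", "epidemic")


def write_density(path, field: DensityField) -> None:
    np.savetxt(path, field.values, fmt="%.17g", delimiter="\t")


def read_density(path, time: int = 0) -> DensityField:
    return DensityField(np.atleast_2d(np.loadtxt(path, delimiter="\t")), time)


@dataclass
class RunConfig:
    """Everything needed to reproduce a simulation run."""

    m: int = 30
    n: int = 30
    offset_parity: str = "odd-column"
    gamma1: float = 0.8
    gamma2: float = 0.8
    phi: float = 1.0 / 3.0
    rho: float = 1.0 / 3.0
    alpha: float = 1.0
    beta: float = 1.0
    xi: float = 1.0
    retention: float = 0.0
    survival_at: str = "prospective"
    bd_b: float = 1.0
    bd_d: float = 0.2
    bd_C: int = 100
    bd_N: int = 100
    bd_M: int = 20
    bd_schedule: str = "none"
    bd_schedule_period: int = 20
    use_microscale: bool = True
    steps: int = 30
    seed: int = 0
    snapshot_times: Optional[List[int]] = None
    initial: str = "single-cell"  # named fixture or a file path
    initial_density: float = 0.5
    barrier_file: Optional[str] = None
    param_rasters: Dict[str, str] = dc_field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def grid(self) -> GridSpec:
        return GridSpec(self.m, self.n, self.offset_parity)

    def params(self) -> ParamField:
        kw = {
            name: getattr(self, name)
            for name in ("gamma1", "gamma2", "phi", "rho", "alpha", "beta", "xi")
        }
        for name, path in self.param_rasters.items():
            if name not in kw:
                raise ValueError(f"unknown parameter raster {name!r}")
            kw[name] = np.loadtxt(path, delimiter="\t")
        return ParamField(
            retention=self.retention, survival_at=self.survival_at, **kw
        )

    def bd(self) -> Optional[BirthDeathSpec]:
        if not self.use_microscale:
            return None
        if self.bd_schedule not in _SCHEDULES:
            raise ValueError(f"bd_schedule must be one of {_SCHEDULES}")
        birth = death = None
        if self.bd_schedule == "sinusoidal":
            birth = sinusoidal_schedule(self.bd_schedule_period)
        elif self.bd_schedule == "endemic":
            birth, death = endemic_schedules(self.bd_schedule_period)
        elif self.bd_schedule == "epidemic":
            birth, death = epidemic_schedules(self.bd_schedule_period)
        return BirthDeathSpec(
            b=self.bd_b,
            d=self.bd_d,
            C=self.bd_C,
            N=self.bd_N,
            M=self.bd_M,
            birth_schedule=birth,
            death_schedule=death,
        )

    def initial_field(self) -> DensityField:
        if self.initial == "single-cell":
            values = np.zeros((self.m, self.n))
            values[self.m // 2, self.n // 2] = self.initial_density
            return DensityField(values)
        return read_density(self.initial)

    def barrier(self) -> Optional[np.ndarray]:
        if self.barrier_file is None:
            return None
        return np.loadtxt(self.barrier_file, delimiter="\t").astype(bool)


def run_multiscale(
    field: DensityField,
    params: ParamField,
    grid: GridSpec,
    bd: Optional[BirthDeathSpec],
    steps: int,
    seed: int,
    barrier: Optional[np.ndarray] = None,
) -> List[DensityField]:
    """Run ``steps`` macro steps, each preceded by the microscale coupling.

    Returns the snapshot list for t = 0..steps (the t = 0 entry is the
    initial field after barrier masking, before any microscale update).
    """
    if barrier is not None:
        barrier = np.asarray(barrier, dtype=bool)
        v = field.values.copy()
        v[barrier] = 0.0
        field = DensityField(v, field.time)
    snapshots = [field]
    current = field
    for t in range(1, steps + 1):
        if bd is not None:
            current = couple_microscale(current, bd, t - 1, seed)
        current, _ = macro_step(current, params, grid, seed, barrier, t=t - 1)
        snapshots.append(current)
    return snapshots


def run_simulation(config: RunConfig, out_dir) -> Path:
    """Execute a configured run; write snapshots, statistics and manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    grid = config.grid()
    params = config.params()
    bd = config.bd()
    barrier = config.barrier()
    field0 = config.initial_field()
    if field0.shape != (config.m, config.n):
        raise ValueError(
            f"initial field shape {field0.shape} does not match grid "
            f"{config.m}x{config.n}"
        )
    snapshots = run_multiscale(
        field0, params, grid, bd, config.steps, config.seed, barrier
    )
    times = config.snapshot_times or list(range(config.steps + 1))
    for t in times:
        write_density(out / f"snapshot_t{t:04d}.txt", snapshots[t])

    rows = []
    for t, snap in enumerate(snapshots):
        nbhds = find_interaction_neighbourhoods(snap, grid)
        for nbhd in nbhds:
            sub = np.zeros_like(snap.values)
            for c in nbhd.affected:
                sub[c.i, c.j] = snap.values[c.i, c.j]
            summary = pattern_summary(DensityField(sub, t), grid)
            rows.append(
                {
                    "time": t,
                    "neighbourhood": nbhd.id,
                    "n_affected": summary.n_affected,
                    "complexity": summary.complexity_edges,
                    "radius": summary.radius,
                    "mean_density": summary.mean_density,
                }
            )
    pd.DataFrame(
        rows,
        columns=[
            "time",
            "neighbourhood",
            "n_affected",
            "complexity",
            "radius",
            "mean_density",
        ],
    ).to_csv(out / "stats.csv", index=False)

    manifest = {"config": config.to_dict(), "version": __version__}
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return out


# ---------------------------------------------------------------------------
# fixtures

def make_fixture(name: str, out_dir, seed: int = 0, **options) -> Dict[str, Path]:
    """Write a named test fixture; returns the files created.

    Fixtures are generated programmatically with a documented, seeded
    construction so no stored data is needed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    m = int(options.get("m", 30))
    n = int(options.get("n", 30))
    grid = GridSpec(m, n)
    files: Dict[str, Path] = {}

    if name == "single-cell":
        values = np.zeros((m, n))
        values[m // 2, n // 2] = float(options.get("density", 0.5))
        path = out / "single_cell.txt"
        write_density(path, DensityField(values))
        files["density"] = path
    elif name == "two-neighbourhoods":
        values = np.zeros((m, n))
        a = grid.cell(m // 2, n // 4)
        b = grid.cell(m // 2, 3 * n // 4)
        if hex_distance(a, b, grid) <= 3:
            raise ValueError("grid too small to separate two neighbourhoods")
        values[a.i, a.j] = 0.6
        values[b.i, b.j] = 0.6
        path = out / "two_neighbourhoods.txt"
        write_density(path, DensityField(values))
        files["density"] = path
    elif name == "random-blob":
        values = np.zeros((m, n))
        ci, cj = m // 2, n // 2
        centre = grid.cell(ci, cj)
        for cell in grid.cells():
            d = hex_distance(centre, cell, grid)
            if d <= 3 and rng.random() < 1.0 - 0.25 * d:
                values[cell.i, cell.j] = rng.uniform(0.2, 1.0)
        values[ci, cj] = max(values[ci, cj], 0.5)
        path = out / "random_blob.txt"
        write_density(path, DensityField(values))
        files["density"] = path
    elif name == "bridge-mask":
        mask = np.zeros((m, n), dtype=int)
        wall = n // 2
        gap = int(options.get("gap", 1))
        mask[:, wall] = 1
        lo = m // 2 - gap // 2
        mask[lo : lo + gap, wall] = 0
        path = out / "bridge_mask.txt"
        np.savetxt(path, mask, fmt="%d", delimiter="\t")
        files["mask"] = path
    elif name == "wind-field":
        # dispersion favoured eastward: beta < 1 raises p_I east of centre,
        # beta > 1 suppresses it to the west
        beta = np.ones((m, n))
        beta[:, : n // 2] = float(options.get("upwind_beta", 2.0))
        beta[:, n // 2 :] = float(options.get("downwind_beta", 0.6))
        path = out / "wind_beta.txt"
        np.savetxt(path, beta, fmt="%.6f", delimiter="\t")
        files["beta"] = path
    elif name == "synthetic-survey-image":
        from PIL import Image

        size = int(options.get("size", 32))
        levels = np.zeros((size, size), dtype=np.uint8)
        ci = cj = size // 2
        radius = size // 4
        for i in range(size):
            for j in range(size):
                if (i - ci) ** 2 + (j - cj) ** 2 <= radius**2:
                    # grey levels 208..248: densities L/256 in [0.8125, 0.969]
                    levels[i, j] = 208 + int(rng.integers(0, 41))
        path = out / "synthetic_survey.png"
        Image.fromarray(levels, mode="L").save(path)
        truth = out / "synthetic_survey_truth.txt"
        np.savetxt(truth, levels / 256.0, fmt="%.17g", delimiter="\t")
        files["image"] = path
        files["truth"] = truth
    else:
        raise ValueError(f"unknown fixture {name!r}")
    return files
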