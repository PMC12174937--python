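"""Pattern statistics of dispersion patterns.

Two equivalent complexity measures quantify how ragged the boundary of an
affected pattern is:

* *edges*: the number of boundary edges (edges of affected cells whose
  opposite cell is not affected, with the domain exterior counting as not
  affected) divided by the number of affected cells ``N_a``;
* *adjacency*: ``(6 N_a - sum_a n_a) / N_a`` where ``n_a`` is the number
  of affected Moore neighbours of affected cell ``a``.

Each affected-to-affected adjacency removes exactly one edge from each of
the two cells' hexagon perimeters, so the two definitions coincide for
every pattern (``6 N_a - sum n_a`` counts perimeter edges not shared with
another affected cell).

The dispersion rate of a neighbourhood is the per-step change of the radius
of the circle with the same area as the affected cells (unit cell area, so
``r = sqrt(N_a / pi)``), centred at the density-weighted centre of mass.

The four calibration summary statistics of a run are (1) the time-average
affected-cell count, (2) the time-average mean density over affected cells,
(3) the time-average complexity and (4) the slope of a least-squares line
through log-complexity versus time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from typing import Dict, Iterable, List, Sequence, Set, Tuple

import numpy as np

from .hexgrid import CellIndex, GridSpec, centroid_xy, moore_neighbors
from .neighbourhoods import DensityField, find_interaction_neighbourhoods

__all__ = [
    "PatternSummary",
    "RateSeries",
    "boundary_edge_count",
    "complexity",
    "equal_area_radius_and_com",
    "dispersion_rate_series",
    "calibration_statistics",
    "pattern_summary",
    "affected_set",
]


@dataclass
class PatternSummary:
    """Summary of one affected pattern at one time."""

    n_affected: int
    boundary_edges: int
    complexity_edges: float
    complexity_adjacency: float
    centre_of_mass: Tuple[float, float]
    radius: float
    mean_density: float
    time: int = 0


@dataclass
class RateSeries:
    """Radius series of one tracked neighbourhood and its first differences."""

    radii: np.ndarray
    t0: int = 0

    @property
    def rates(self) -> np.ndarray:
        return np.diff(self.radii)


def _as_cells(affected: Iterable) -> Set[CellIndex]:
    out = set()
    for c in affected:
        if isinstance(c, CellIndex):
            out.add(CellIndex(c.i, c.j))
        else:
            i, j = c
            out.add(CellIndex(int(i), int(j)))
    return out


def affected_set(field: DensityField) -> Set[CellIndex]:
    ii, jj = np.nonzero(field.values > 0)
    return {CellIndex(int(a), int(b)) for a, b in zip(ii, jj)}


def boundary_edge_count(affected: Iterable, grid: GridSpec) -> int:
    """Edges of affected cells whose opposite cell is not affected."""
    cells = _as_cells(affected)
    if not cells:
        raise ValueError("boundary_edge_count requires a non-empty pattern")
    count = 0
    for cell in cells:
        for nb in moore_neighbors(cell, grid):
            if CellIndex(nb.i, nb.j) not in cells:
                count += 1
    return count


def complexity(affected: Iterable, grid: GridSpec, method: str = "edges") -> float:
    cells = _as_cells(affected)
    if not cells:
        raise ValueError("complexity requires a non-empty pattern")
    na = len(cells)
    if method == "edges":
        return boundary_edge_count(cells, grid) / na
    if method == "adjacency":
        total_adjacent = 0
        for cell in cells:
            total_adjacent += sum(
                1 for nb in moore_neighbors(cell, grid) if CellIndex(nb.i, nb.j) in cells
            )
        return (6 * na - total_adjacent) / na
    raise ValueError("method must be 'edges' or 'adjacency'")


def equal_area_radius_and_com(
    affected: Iterable, field: DensityField, grid: GridSpec
) -> Tuple[float, Tuple[float, float]]:
    """Equal-area-circle radius and density-weighted centre of mass.

    Uses unit cell area, so ``r = sqrt(N_a / pi)``.
    """
    cells = _as_cells(affected)
    if not cells:
        raise ValueError("pattern has no affected cells")
    total = 0.0
    cx = cy = 0.0
    for cell in cells:
        w = float(field.values[cell.i, cell.j])
        x, y = centroid_xy(cell, grid)
        cx += w * x
        cy += w * y
        total += w
    if total <= 0:
        raise ValueError("all densities are zero; centre of mass undefined")
    radius = math.sqrt(len(cells) / math.pi)
    return radius, (cx / total, cy / total)


def pattern_summary(field: DensityField, grid: GridSpec) -> PatternSummary:
    """Summary of the whole affected pattern of a snapshot."""
    cells = affected_set(field)
    if not cells:
        raise ValueError("snapshot has no affected cells")
    na = len(cells)
    edges = boundary_edge_count(cells, grid)
    radius, com = equal_area_radius_and_com(cells, field, grid)
    dens = np.array([field.values[c.i, c.j] for c in cells])
    return PatternSummary(
        n_affected=na,
        boundary_edges=edges,
        complexity_edges=edges / na,
        complexity_adjacency=complexity(cells, grid, "adjacency"),
        centre_of_mass=com,
        radius=radius,
        mean_density=float(dens.mean()),
        time=field.time,
    )


def dispersion_rate_series(
    snapshots: Sequence[DensityField], grid: GridSpec
) -> Dict[int, RateSeries]:
    """Per-neighbourhood radius series across a sequence of snapshots.

    Neighbourhood identity over time uses maximal-overlap matching of
    affected sets; when neighbourhoods merge, the merged neighbourhood
    inherits the larger parent's series.  A neighbourhood that vanishes
    terminates its series at that time.
    """
    if len(snapshots) < 2:
        raise ValueError("need at least two snapshots")
    series: Dict[int, List[float]] = {}
    starts: Dict[int, int] = {}
    next_id = 0
    prev: List[Tuple[int, Set[CellIndex]]] = []
    for t, field in enumerate(snapshots):
        current = find_interaction_neighbourhoods(field, grid)
        taken: Set[int] = set()
        new_prev = []
        for nbhd in current:
            aff = set(nbhd.affected)
            best_id, best_size = None, -1
            for pid, paff in prev:
                if pid in taken:
                    continue
                if aff & paff and len(paff) > best_size:
                    best_id, best_size = pid, len(paff)
            if best_id is None:
                best_id = next_id
                next_id += 1
                starts[best_id] = t
                series[best_id] = []
            taken.add(best_id)
            series[best_id].append(math.sqrt(len(aff) / math.pi))
            new_prev.append((best_id, aff))
        prev = new_prev
    return {
        k: RateSeries(np.asarray(v), t0=starts[k]) for k, v in series.items() if v
    }


def calibration_statistics(
    snapshots: Sequence[DensityField], grid: GridSpec
) -> np.ndarray:
    """The four run-level summary statistics used for calibration.

    Returns ``[mean N_a, mean affected-cell density, mean complexity,
    log-complexity slope]``.  Averages run over snapshots; the density and
    complexity averages skip times with no affected cells, while the
    affected-count average includes them.  Raises if the run never has an
    affected cell or log-complexity cannot be fit (fewer than two non-empty
    snapshots).
    """
    n_aff = []
    densities = []
    complexities = []
    times = []
    for t, field in enumerate(snapshots):
        cells = affected_set(field)
        n_aff.append(len(cells))
        if not cells:
            continue
        vals = np.array([field.values[c.i, c.j] for c in cells])
        densities.append(vals.mean())
        complexities.append(boundary_edge_count(cells, grid) / len(cells))
        times.append(t)
    if not densities:
        raise ValueError("run has no affected cells; statistics undefined")
    if len(times) < 2:
        raise ValueError("need at least two non-empty snapshots for the slope")
    slope = np.polyfit(np.asarray(times, dtype=float), np.log(complexities), 1)[0]
    return np.array(
        [
            float(np.mean(n_aff)),
            float(np.mean(densities)),
            float(np.mean(complexities)),
            float(slope),
        ]
    )
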