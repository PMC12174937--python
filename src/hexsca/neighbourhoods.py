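"""Interaction neighbourhoods and inclusion weights.

An *affected* cell is a cell with strictly positive density (exactly
``pi > 0``; the dispersion update zeroes cells exactly, so 0 is an
attainable, meaningful state).  Affected cells that are not separated by
more than two unaffected cells interact: the transitive closure of pairwise
``hex_distance <= 3`` partitions the affected cells into *interaction
neighbourhoods*.  Each neighbourhood carries its *halo* — the unaffected
immediate Moore neighbours of its affected members, which may include
auxiliary (off-grid) cells.  Dispersion in distinct neighbourhoods is
independent.

Inclusion weights follow the counting rule: an affected cell's weight is its
number of adjacent affected neighbours plus one; an unaffected (halo) cell's
weight is its number of adjacent affected neighbours.  ``d`` is the maximum
absolute density difference between a cell and its six neighbours
(auxiliary neighbours carry density 0), which for a halo cell reduces to
the largest neighbouring density.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Dict, FrozenSet, List, Optional

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .hexgrid import CellIndex, GridSpec, moore_neighbors

__all__ = [
    "DensityField",
    "InteractionNeighbourhood",
    "InclusionWeights",
    "find_interaction_neighbourhoods",
    "inclusion_weights",
]

#: grouping bound: affected cells within this hex distance interact
SEPARATION_DISTANCE = 3


@dataclass
class DensityField:
    """Normalized population densities on the grid at macro time ``time``."""

    values: np.ndarray
    time: int = 0

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("density field must be a 2-D matrix")
        if v.min() < -1e-12 or v.max() > 1.0 + 1e-12:
            raise ValueError("densities must lie in [0, 1]")
        self.values = np.clip(v, 0.0, 1.0)

    @property
    def shape(self):
        return self.values.shape

    def copy(self) -> "DensityField":
        return DensityField(self.values.copy(), self.time)


@dataclass(frozen=True)
class InteractionNeighbourhood:
    """A group of interacting affected cells plus their unaffected halo."""

    affected: FrozenSet[CellIndex]
    halo: FrozenSet[CellIndex]
    id: int

    @property
    def members(self) -> FrozenSet[CellIndex]:
        return self.affected | self.halo

    @property
    def anchor(self) -> CellIndex:
        """Lexicographically smallest affected cell; stable RNG key."""
        return min(self.affected)


@dataclass
class InclusionWeights:
    w: Dict[CellIndex, int] = dc_field(default_factory=dict)
    d: Dict[CellIndex, float] = dc_field(default_factory=dict)


def _offset_to_cube_arrays(ii: np.ndarray, jj: np.ndarray, parity: str):
    if parity == "odd-column":
        z = ii - (jj - (jj & 1)) // 2
    else:
        z = ii - (jj + (jj & 1)) // 2
    x = jj
    return x, -x - z, z


def find_interaction_neighbourhoods(
    field: DensityField,
    grid: GridSpec,
    barrier: Optional[np.ndarray] = None,
) -> List[InteractionNeighbourhood]:
    """Partition affected cells into interaction neighbourhoods.

    Barrier cells (mask True) are permanently unavailable: they are never
    affected, never halo members, and never receive density.
    """
    values = field.values
    mask = values > 0.0
    if barrier is not None:
        mask = mask & ~np.asarray(barrier, dtype=bool)
    ii, jj = np.nonzero(mask)
    na = ii.size
    if na == 0:
        return []

    x, y, z = _offset_to_cube_arrays(ii, jj, grid.offset_parity)
    # pairwise hex distance via cube coordinates; grids are small (<= ~10^4
    # cells per the intended problem sizes), so the dense matrix is fine
    dist = (
        np.abs(x[:, None] - x[None, :])
        + np.abs(y[:, None] - y[None, :])
        + np.abs(z[:, None] - z[None, :])
    ) // 2
    adj = csr_matrix(dist <= SEPARATION_DISTANCE)
    n_comp, labels = connected_components(adj, directed=False)

    affected_all = {CellIndex(int(a), int(b)) for a, b in zip(ii, jj)}
    barrier_set = set()
    if barrier is not None:
        bi, bj = np.nonzero(np.asarray(barrier, dtype=bool))
        barrier_set = {(int(a), int(b)) for a, b in zip(bi, bj)}

    groups: Dict[int, List[CellIndex]] = {}
    for a, b, lab in zip(ii, jj, labels):
        groups.setdefault(int(lab), []).append(CellIndex(int(a), int(b)))

    # stable ids: order components by their smallest affected cell
    ordered = sorted(groups.values(), key=min)
    out: List[InteractionNeighbourhood] = []
    for nid, cells in enumerate(ordered):
        aff = frozenset(cells)
        halo = set()
        for c in cells:
            for nb in moore_neighbors(c, grid):
                if nb in aff:
                    continue
                if (nb.i, nb.j) in barrier_set:
                    continue
                halo.add(nb)
        out.append(InteractionNeighbourhood(aff, frozenset(halo), nid))
    return out


def _density(cell: CellIndex, values: np.ndarray) -> float:
    if cell.is_auxiliary:
        return 0.0
    return float(values[cell.i, cell.j])


def inclusion_weights(
    nbhd: InteractionNeighbourhood,
    field: DensityField,
    grid: GridSpec,
) -> InclusionWeights:
    """Inclusion weights ``w`` and maximum density differences ``d``.

    Auxiliary halo cells are handled like any unaffected cell with density
    zero; their weight counts their affected neighbours on the grid.
    """
    values = field.values
    aff = nbhd.affected
    weights = InclusionWeights()
    for cell in nbhd.members:
        if cell.is_auxiliary:
            # neighbours of an off-grid cell: enumerate via cube geometry of
            # the real neighbours; only on-grid affected neighbours count
            from .hexgrid import CUBE_DIRECTIONS, cube_to_offset, offset_to_cube

            x, _, z = offset_to_cube(cell.i, cell.j, grid.offset_parity)
            nbs = [
                grid.cell(*cube_to_offset(x + dx, z + dz, grid.offset_parity))
                for dx, _, dz in CUBE_DIRECTIONS
            ]
        else:
            nbs = moore_neighbors(cell, grid)
        n_aff = sum(1 for nb in nbs if nb in aff)
        w = n_aff + 1 if cell in aff else n_aff
        pi_c = _density(cell, values)
        d = max(abs(pi_c - _density(nb, values)) for nb in nbs)
        weights.w[cell] = w
        weights.d[cell] = d
    return weights
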