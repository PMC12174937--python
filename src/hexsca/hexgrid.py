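"""Hexagonal-lattice geometry.

The spatial domain is an ``m x n`` partition of uniformly sized flat-top
hexagonal cells addressed by 0-based offset coordinates ``(i, j)`` (row,
column).  The package fixes the *odd-column-shifted* ("odd-q") convention:
cells in odd columns sit half a cell lower than cells in even columns.  Any
consistent convention reproduces the same dynamics; fixing one makes every
neighbour list, distance and centroid deterministic.

Cells one step outside the grid boundary are *auxiliary* cells.  They are
materialized as ordinary :class:`CellIndex` objects (flagged
``is_auxiliary``) so that the absorbing boundary condition can be accounted
exactly: auxiliary cells can receive dispersed density but never hold or
return it.

All geometry goes through cube coordinates ``(x, y, z)`` with
``x + y + z = 0``, which makes neighbour enumeration, distances and
straight lines trivial.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import sqrt
from typing import Iterator, List, Tuple

__all__ = [
    "CellIndex",
    "GridSpec",
    "moore_neighbors",
    "hex_distance",
    "centroid_xy",
    "offset_to_cube",
    "cube_to_offset",
]

#: Unit cube-coordinate displacements in cyclic order.  Consecutive entries
#: (cyclically) are themselves adjacent, so a cell's six Moore neighbours are
#: returned walking once around the cell.
CUBE_DIRECTIONS: Tuple[Tuple[int, int, int], ...] = (
    (1, -1, 0),
    (1, 0, -1),
    (0, 1, -1),
    (-1, 1, 0),
    (-1, 0, 1),
    (0, -1, 1),
)

_PARITIES = ("odd-column", "even-column")

# horizontal centroid spacing for unit centre-to-centre distance
_XSTEP = sqrt(3.0) / 2.0


@dataclass(frozen=True, order=True)
class CellIndex:
    """A cell address ``(i, j)``; ``is_auxiliary`` marks off-grid cells."""

    i: int
    j: int
    is_auxiliary: bool = False


@dataclass(frozen=True)
class GridSpec:
    """Dimensions and offset convention of the hexagonal grid."""

    m: int
    n: int
    offset_parity: str = "odd-column"

    def __post_init__(self) -> None:
        if self.m < 1 or self.n < 1:
            raise ValueError(f"grid dimensions must be positive, got {self.m}x{self.n}")
        if self.offset_parity not in _PARITIES:
            raise ValueError(f"offset_parity must be one of {_PARITIES}")

    def contains(self, i: int, j: int) -> bool:
        return 0 <= i < self.m and 0 <= j < self.n

    def cell(self, i: int, j: int) -> CellIndex:
        """Build a :class:`CellIndex` with the auxiliary flag set correctly."""
        return CellIndex(int(i), int(j), not self.contains(i, j))

    def cells(self) -> Iterator[CellIndex]:
        """Iterate over all real cells in row-major order."""
        for i in range(self.m):
            for j in range(self.n):
                yield CellIndex(i, j)

    def is_boundary(self, cell: CellIndex) -> bool:
        """True if any Moore neighbour of ``cell`` lies off the grid."""
        return any(nb.is_auxiliary for nb in moore_neighbors(cell, self))


def offset_to_cube(i: int, j: int, parity: str = "odd-column") -> Tuple[int, int, int]:
    if parity == "odd-column":
        z = i - (j - (j & 1)) // 2
    else:
        z = i - (j + (j & 1)) // 2
    x = j
    return x, -x - z, z


def cube_to_offset(x: int, z: int, parity: str = "odd-column") -> Tuple[int, int]:
    j = x
    if parity == "odd-column":
        i = z + (j - (j & 1)) // 2
    else:
        i = z + (j + (j & 1)) // 2
    return i, j


# Neighbour lists are pure geometry and heavily reused in the hot loops of a
# dispersion step; memoize them per (grid, cell).
_NEIGHBOR_CACHE: dict = {}


def moore_neighbors(cell: CellIndex, grid: GridSpec) -> List[CellIndex]:
    """The six adjacent cells of ``cell`` in a fixed cyclic order.

    Off-grid positions are returned as auxiliary cells, so the list always
    has length six.  Raises ``IndexError`` for a cell outside the grid.
    """
    key = (grid.m, grid.n, grid.offset_parity, cell.i, cell.j)
    cached = _NEIGHBOR_CACHE.get(key)
    if cached is not None:
        return cached
    if not grid.contains(cell.i, cell.j):
        raise IndexError(f"cell ({cell.i}, {cell.j}) outside {grid.m}x{grid.n} grid")
    x, _, z = offset_to_cube(cell.i, cell.j, grid.offset_parity)
    out = []
    for dx, _, dz in CUBE_DIRECTIONS:
        ni, nj = cube_to_offset(x + dx, z + dz, grid.offset_parity)
        out.append(grid.cell(ni, nj))
    _NEIGHBOR_CACHE[key] = out
    return out


def hex_distance(a: CellIndex, b: CellIndex, grid: GridSpec) -> int:
    """Length of the shortest adjacency path between two cells."""
    ax, ay, az = offset_to_cube(a.i, a.j, grid.offset_parity)
    bx, by, bz = offset_to_cube(b.i, b.j, grid.offset_parity)
    return (abs(ax - bx) + abs(ay - by) + abs(az - bz)) // 2


def centroid_xy(cell: CellIndex, grid: GridSpec) -> Tuple[float, float]:
    """Planar centroid with unit distance between adjacent centroids."""
    if grid.offset_parity == "odd-column":
        shift = 0.5 * (cell.j & 1)
    else:
        shift = 0.5 * ((cell.j + 1) & 1)
    return (_XSTEP * cell.j, cell.i + shift)
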