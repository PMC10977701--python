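"""The 3-D cubic occupancy grid and the division-placement rules.

Coordinates are 0-based integer triples ``(x, y, z)`` with ``z = 0`` the
bottom (inoculated) layer; the lattice spans ``[0, n_c) x [0, n_c) x
[0, n_z)``.  Each site holds at most one cell (``EMPTY``, ``SLOW`` or
``FAST``).

Division placement follows two rules:

* horizontal, if any empty site exists in the mother's z-plane within
  Chebyshev radius ``r_d``: the nearest empty site is targeted (ties
  broken uniformly at random), the occupants along the discretized
  mother→target line are shoved one step outward, and the daughter
  appears on the vacated site next to the mother;
* vertical otherwise: the contiguous stack above the mother is pushed
  up one site and the daughter is placed directly above her.

The lattice also maintains cached per-site neighbor counts at the
interaction radius so the simulation loop can evaluate occupancy
fractions in O(1); :func:`local_occupancy` deliberately ignores the
cache and recounts from the grid, which makes it the independent check
used by the tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Optional

import numpy as np

from . import _kernel
from .model import CellType, Occupancy

EMPTY = 0

Coordinate = tuple[int, int, int]


class LatticeError(Exception):
    """Invalid coordinate or precondition violation on the lattice."""


class ColumnOverflowError(LatticeError):
    """A vertical division found no empty site below the lattice ceiling."""


@dataclass(frozen=True)
class PlacementPlan:
    """Where a daughter cell will go: horizontally toward ``target``
    (shoving as needed) or vertically above the mother."""

    vertical: bool
    target: Optional[Coordinate] = None

    @property
    def horizontal(self) -> bool:
        return not self.vertical


class ColonyLattice:
    """Occupancy grid plus flat per-cell coordinate arrays.

    Parameters
    ----------
    n_c
        Lateral extent in sites (the grid base is ``n_c x n_c``).
    n_z
        Height in sites.
    r_i
        Interaction radius at which the cached neighbor counts are
        maintained.
    capacity
        Size of the per-cell coordinate arrays; defaults to the full
        site count ``n_c * n_c * n_z``.
    """

    def __init__(self, n_c: int = 50, n_z: int = 100, r_i: int = 3,
                 capacity: Optional[int] = None):
        if n_c < 1 or n_z < 1 or r_i < 1:
            raise ValueError("n_c, n_z and r_i must be >= 1")
        self.n_c = int(n_c)
        self.n_z = int(n_z)
        self.r_i = int(r_i)
        n_sites = self.n_c * self.n_c * self.n_z
        if capacity is None:
            capacity = n_sites
        capacity = min(int(capacity), n_sites)
        shape = (self.n_c, self.n_c, self.n_z)
        self.grid = np.zeros(shape, dtype=np.int8)
        self.count_slow = np.zeros(shape, dtype=np.int32)
        self.count_fast = np.zeros(shape, dtype=np.int32)
        self.cell_index = np.full(shape, -1, dtype=np.int32)
        self.denom = _neighborhood_sizes(self.n_c, self.n_z, self.r_i)
        self.xs = np.zeros(capacity, dtype=np.int32)
        self.ys = np.zeros(capacity, dtype=np.int32)
        self.zs = np.zeros(capacity, dtype=np.int32)
        self.types = np.zeros(capacity, dtype=np.int8)
        self.n_cells = 0

    # -- basic queries -------------------------------------------------

    @property
    def capacity(self) -> int:
        return self.xs.shape[0]

    def in_bounds(self, pos: Coordinate) -> bool:
        x, y, z = pos
        return 0 <= x < self.n_c and 0 <= y < self.n_c and 0 <= z < self.n_z

    def _check_bounds(self, pos: Coordinate) -> None:
        if not self.in_bounds(pos):
            raise LatticeError(f"position {pos} outside the lattice")

    def site(self, pos: Coordinate) -> int:
        self._check_bounds(pos)
        return int(self.grid[pos])

    def counts(self) -> tuple[int, int]:
        """(n_slow, n_fast) among the cells currently on the lattice."""
        t = self.types[: self.n_cells]
        n_slow = int(np.count_nonzero(t == int(CellType.SLOW)))
        return n_slow, self.n_cells - n_slow

    def positions(self) -> np.ndarray:
        """(n_cells, 3) array of occupied coordinates, in placement order."""
        n = self.n_cells
        return np.column_stack((self.xs[:n], self.ys[:n], self.zs[:n]))

    # -- mutation ------------------------------------------------------

    def place(self, pos: Coordinate, cell: CellType) -> None:
        """Put a new cell on an empty site."""
        self._check_bounds(pos)
        if self.grid[pos] != EMPTY:
            raise LatticeError(f"site {pos} already occupied")
        if self.n_cells >= self.capacity:
            raise LatticeError("cell arrays exhausted; raise capacity")
        x, y, z = pos
        self.n_cells = _kernel.place_cell(
            self.grid, self.count_slow, self.count_fast, self.cell_index,
            self.xs, self.ys, self.zs, self.types, self.n_cells,
            x, y, z, int(cell), self.r_i, self.n_c, self.n_z)

    def audit(self) -> None:
        """Full-lattice consistency check (used by the tests).

        Verifies site exclusivity (grid vs. flat arrays), the cell
        count, and the cached neighbor counts against a brute-force
        recount.  Raises AssertionError on any mismatch.
        """
        n = self.n_cells
        assert int(np.count_nonzero(self.grid)) == n
        occ = np.zeros_like(self.grid, dtype=bool)
        for i in range(n):
            p = (int(self.xs[i]), int(self.ys[i]), int(self.zs[i]))
            assert not occ[p], f"two cells at {p}"
            occ[p] = True
            assert self.grid[p] == self.types[i]
            assert self.cell_index[p] == i
        slow = (self.grid == int(CellType.SLOW)).astype(np.int32)
        fast = (self.grid == int(CellType.FAST)).astype(np.int32)
        assert np.array_equal(_box_sum(slow, self.r_i), self.count_slow)
        assert np.array_equal(_box_sum(fast, self.r_i), self.count_fast)


def _neighborhood_sizes(n_c: int, n_z: int, r: int) -> np.ndarray:
    """Number of in-lattice sites in the cubic box of radius ``r`` around
    each site, excluding the center (the occupancy denominator)."""
    def extent(n: int) -> np.ndarray:
        i = np.arange(n)
        return np.minimum(i + r, n - 1) - np.maximum(i - r, 0) + 1

    ex = extent(n_c)
    ez = extent(n_z)
    return (ex[:, None, None] * ex[None, :, None] * ez[None, None, :]
            - 1).astype(np.int32)


def _box_sum(a: np.ndarray, r: int) -> np.ndarray:
    """Sum of ``a`` over the in-lattice cubic box of radius ``r`` at each
    site (center included); brute-force via cumulative sums."""
    out = a
    for axis in range(3):
        c = np.cumsum(out, axis=axis)
        c = np.concatenate([np.zeros_like(np.take(c, [0], axis=axis)), c],
                           axis=axis)
        n = a.shape[axis]
        hi = np.minimum(np.arange(n) + r + 1, n)
        lo = np.maximum(np.arange(n) - r, 0)
        out = np.take(c, hi, axis=axis) - np.take(c, lo, axis=axis)
    return out


# -- spec operations ---------------------------------------------------

def iter_neighborhood(lat: ColonyLattice, pos: Coordinate, radius: int,
                      plane_restricted: bool = False) -> Iterator[Coordinate]:
    """In-lattice sites within Chebyshev ``radius`` of ``pos``, excluding
    ``pos`` itself; optionally restricted to the center's z-plane."""
    x, y, z = pos
    z0, z1 = (z, z) if plane_restricted else (
        max(0, z - radius), min(lat.n_z - 1, z + radius))
    for xx in range(max(0, x - radius), min(lat.n_c - 1, x + radius) + 1):
        for yy in range(max(0, y - radius), min(lat.n_c - 1, y + radius) + 1):
            for zz in range(z0, z1 + 1):
                if (xx, yy, zz) != pos:
                    yield (xx, yy, zz)


def local_occupancy(lat: ColonyLattice, pos: Coordinate,
                    r_i: Optional[int] = None) -> Occupancy:
    """Occupancy fractions of the cubic interaction neighborhood.

    Counts only in-lattice sites and excludes the focal site, so the
    denominator shrinks at edges and corners.  This recounts directly
    from the grid (it does not consult the cached counts).
    """
    lat._check_bounds(pos)
    if r_i is None:
        r_i = lat.r_i
    if r_i < 1:
        raise ValueError("r_i must be >= 1")
    n_sites = 0
    n_slow = 0
    n_fast = 0
    for site in iter_neighborhood(lat, pos, r_i):
        n_sites += 1
        v = lat.grid[site]
        if v == int(CellType.SLOW):
            n_slow += 1
        elif v == int(CellType.FAST):
            n_fast += 1
    return Occupancy(phi_s=n_slow / n_sites, phi_f=n_fast / n_sites)


def find_division_target(lat: ColonyLattice, mother: Coordinate, r_d: int,
                         rng: np.random.Generator) -> PlacementPlan:
    """Choose where a daughter of the cell at ``mother`` will go.

    Searches the mother's z-plane within Chebyshev radius ``r_d``; if
    empty sites exist, one at minimal Chebyshev distance is picked
    uniformly at random, giving a horizontal plan.  A fully occupied
    plane neighborhood yields a vertical plan.  Does not mutate the
    lattice.
    """
    lat._check_bounds(mother)
    if lat.grid[mother] == EMPTY:
        raise LatticeError(f"mother site {mother} is empty")
    candidates: list[Coordinate] = []
    best = r_d + 1
    for site in iter_neighborhood(lat, mother, r_d, plane_restricted=True):
        if lat.grid[site] != EMPTY:
            continue
        d = max(abs(site[0] - mother[0]), abs(site[1] - mother[1]))
        if d < best:
            best = d
            candidates = [site]
        elif d == best:
            candidates.append(site)
    if not candidates:
        return PlacementPlan(vertical=True)
    target = candidates[int(rng.integers(len(candidates)))]
    return PlacementPlan(vertical=False, target=target)


def shove_path(mother: Coordinate, target: Coordinate) -> list[Coordinate]:
    """Discretized straight line from mother toward target (exclusive of
    the mother, inclusive of the target), one Chebyshev step per site."""
    dx = target[0] - mother[0]
    dy = target[1] - mother[1]
    dist = max(abs(dx), abs(dy))
    z = mother[2]
    return [
        (mother[0] + int(np.floor(k * dx / dist + 0.5)),
         mother[1] + int(np.floor(k * dy / dist + 0.5)),
         z)
        for k in range(1, dist + 1)
    ]


def execute_horizontal(lat: ColonyLattice, mother: Coordinate,
                       target: Coordinate, cell: CellType,
                       rng: Optional[np.random.Generator] = None) -> Coordinate:
    """Divide horizontally: shove occupants along the mother→target line
    one step outward and place the daughter next to the mother.

    Returns the daughter's coordinate.  ``rng`` is accepted for
    interface symmetry; the shove itself is deterministic.
    """
    lat._check_bounds(mother)
    lat._check_bounds(target)
    if lat.grid[mother] == EMPTY:
        raise LatticeError(f"mother site {mother} is empty")
    if lat.grid[target] != EMPTY:
        raise LatticeError(f"target site {target} is occupied")
    if target[2] != mother[2]:
        raise LatticeError("horizontal division requires same z-plane")
    if lat.n_cells >= lat.capacity:
        raise LatticeError("cell arrays exhausted; raise capacity")
    lat.n_cells = _kernel.divide_horizontal(
        lat.grid, lat.count_slow, lat.count_fast, lat.cell_index,
        lat.xs, lat.ys, lat.zs, lat.types, lat.n_cells,
        mother[0], mother[1], mother[2], target[0], target[1],
        int(cell), lat.r_i, lat.n_c, lat.n_z)
    return shove_path(mother, target)[0]


def execute_vertical(lat: ColonyLattice, mother: Coordinate,
                     cell: CellType) -> Coordinate:
    """Divide vertically: push the contiguous stack above the mother up
    one site and place the daughter directly above her."""
    lat._check_bounds(mother)
    if lat.grid[mother] == EMPTY:
        raise LatticeError(f"mother site {mother} is empty")
    if lat.n_cells >= lat.capacity:
        raise LatticeError("cell arrays exhausted; raise capacity")
    n, status = _kernel.divide_vertical(
        lat.grid, lat.count_slow, lat.count_fast, lat.cell_index,
        lat.xs, lat.ys, lat.zs, lat.types, lat.n_cells,
        mother[0], mother[1], mother[2], int(cell),
        lat.r_i, lat.n_c, lat.n_z)
    if status == _kernel.STATUS_OVERFLOW:
        raise ColumnOverflowError(
            f"column above {mother} is full to the lattice ceiling")
    lat.n_cells = n
    return (mother[0], mother[1], mother[2] + 1)
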