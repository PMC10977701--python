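"""Occupancy queries, division-target search, shoving, and stacking."""

import numpy as np
import pytest

from beardsim import (CellType, ColonyLattice, ColumnOverflowError,
                      LatticeError, execute_horizontal, execute_vertical,
                      find_division_target, local_occupancy)
from beardsim.lattice import iter_neighborhood, shove_path

from conftest import build_lattice, random_lattice


def occupied_multiset(lat):
    """Sorted (type, count) pairs of all cells on the lattice."""
    vals, counts = np.unique(lat.grid[lat.grid != 0], return_counts=True)
    return dict(zip(vals.tolist(), counts.tolist()))


class TestLocalOccupancy:
    def test_empty_lattice(self):
        lat = ColonyLattice(n_c=20, n_z=10)
        occ = local_occupancy(lat, (10, 10, 5), 3)
        assert (occ.phi_s, occ.phi_f) == (0.0, 0.0)

    def test_full_interior_neighborhood(self):
        """342 slow neighbors in the full 7^3 - 1 interior box."""
        lat = ColonyLattice(n_c=20, n_z=10)
        center = (10, 10, 5)
        for site in iter_neighborhood(lat, center, 3):
            lat.place(site, CellType.SLOW)
        occ = local_occupancy(lat, center, 3)
        assert (occ.phi_s, occ.phi_f) == (1.0, 0.0)
        assert sum(1 for _ in iter_neighborhood(lat, center, 3)) == 342

    def test_corner_denominator_shrinks(self):
        """At the corner the radius-3 box has 4*4*4 - 1 = 63 in-lattice
        sites; fractions are over those only."""
        cells = {}
        sites = list(iter_neighborhood(ColonyLattice(20, 10), (0, 0, 0), 3))
        assert len(sites) == 63
        for site in sites[:5]:
            cells[site] = CellType.SLOW
        for site in sites[5:8]:
            cells[site] = CellType.FAST
        lat = build_lattice(cells)
        occ = local_occupancy(lat, (0, 0, 0), 3)
        assert occ.phi_s == pytest.approx(5 / 63)
        assert occ.phi_f == pytest.approx(3 / 63)

    def test_excludes_focal_cell(self):
        lat = build_lattice({(10, 10, 5): CellType.SLOW})
        occ = local_occupancy(lat, (10, 10, 5), 3)
        assert (occ.phi_s, occ.phi_f) == (0.0, 0.0)

    def test_out_of_bounds_position_rejected(self):
        lat = ColonyLattice(n_c=10, n_z=5)
        with pytest.raises(LatticeError):
            local_occupancy(lat, (10, 0, 0), 3)

    def test_matches_cached_counts_on_random_lattices(self, rng):
        """The incrementally maintained counts agree with the
        brute-force recount at every occupied site."""
        for _ in range(5):
            lat = random_lattice(rng, fill=0.4)
            for i in range(lat.n_cells):
                pos = (int(lat.xs[i]), int(lat.ys[i]), int(lat.zs[i]))
                occ = local_occupancy(lat, pos)
                n_s = lat.count_slow[pos] - (lat.types[i] == 1)
                n_f = lat.count_fast[pos] - (lat.types[i] == 2)
                den = lat.denom[pos]
                assert occ.phi_s == pytest.approx(n_s / den)
                assert occ.phi_f == pytest.approx(n_f / den)


class TestFindDivisionTarget:
    def test_lone_cell_divides_to_adjacent_site(self, rng):
        lat = build_lattice({(10, 10, 0): CellType.SLOW})
        plan = find_division_target(lat, (10, 10, 0), 3, rng)
        assert plan.horizontal
        d = max(abs(plan.target[0] - 10), abs(plan.target[1] - 10))
        assert d == 1 and plan.target[2] == 0

    def test_full_plane_neighborhood_goes_vertical(self, rng):
        cells = {(10, 10, 0): CellType.SLOW}
        lat0 = ColonyLattice(20, 10)
        for site in iter_neighborhood(lat0, (10, 10, 0), 3,
                                      plane_restricted=True):
            cells[site] = CellType.FAST
        lat = build_lattice(cells)
        plan = find_division_target(lat, (10, 10, 0), 3, rng)
        assert plan.vertical

    def test_single_distant_empty_site_is_found(self, rng):
        """With the ring of 48 nearer sites occupied, the unique empty
        site at Chebyshev distance 3 is the target."""
        cells = {(10, 10, 0): CellType.SLOW}
        lat0 = ColonyLattice(20, 10)
        hole = (13, 12, 0)
        for site in iter_neighborhood(lat0, (10, 10, 0), 3,
                                      plane_restricted=True):
            if site != hole:
                cells[site] = CellType.FAST
        lat = build_lattice(cells)
        plan = find_division_target(lat, (10, 10, 0), 3, rng)
        assert plan.horizontal and plan.target == hole

    def test_empty_mother_rejected(self, rng):
        lat = ColonyLattice(20, 10)
        with pytest.raises(LatticeError):
            find_division_target(lat, (5, 5, 0), 3, rng)

    def test_equivalent_to_exhaustive_search(self, rng):
        """On randomized lattices the plan is vertical iff no in-plane
        empty site exists within the radius, and a horizontal target is
        an empty site at the exhaustively-found minimal distance."""
        for _ in range(200):
            lat = random_lattice(rng, n_c=9, n_z=4, fill=rng.uniform(0.2, 1))
            if lat.n_cells == 0:
                continue
            i = int(rng.integers(lat.n_cells))
            mother = (int(lat.xs[i]), int(lat.ys[i]), int(lat.zs[i]))
            empties = [
                s for s in iter_neighborhood(lat, mother, 3,
                                             plane_restricted=True)
                if lat.grid[s] == 0
            ]
            plan = find_division_target(lat, mother, 3, rng)
            if not empties:
                assert plan.vertical
            else:
                best = min(max(abs(s[0] - mother[0]), abs(s[1] - mother[1]))
                           for s in empties)
                assert plan.horizontal
                assert lat.grid[plan.target] == 0
                assert max(abs(plan.target[0] - mother[0]),
                           abs(plan.target[1] - mother[1])) == best

    def test_tie_break_is_uniformish(self, rng):
        """A lone cell has 8 equidistant empty neighbors; each should be
        drawn with roughly equal frequency."""
        lat = build_lattice({(10, 10, 0): CellType.SLOW})
        counts = {}
        n = 4000
        for _ in range(n):
            plan = find_division_target(lat, (10, 10, 0), 3, rng)
            counts[plan.target] = counts.get(plan.target, 0) + 1
        assert len(counts) == 8
        for c in counts.values():  # ~6 sigma band around n/8
            assert abs(c - n / 8) < 6 * np.sqrt(n * (1 / 8) * (7 / 8))


class TestExecuteHorizontal:
    def test_adjacent_target_no_shove(self, rng):
        lat = build_lattice({(10, 10, 0): CellType.SLOW})
        daughter = execute_horizontal(lat, (10, 10, 0), (11, 10, 0),
                                      CellType.SLOW, rng)
        assert daughter == (11, 10, 0)
        assert lat.n_cells == 2
        assert lat.grid[11, 10, 0] == 1
        lat.audit()

    def test_single_axis_chain_shove(self, rng):
        """Occupants between mother and target shift one site outward;
        the daughter lands next to the mother."""
        lat = build_lattice({(10, 10, 0): CellType.SLOW,
                             (11, 10, 0): CellType.FAST,
                             (12, 10, 0): CellType.SLOW})
        daughter = execute_horizontal(lat, (10, 10, 0), (13, 10, 0),
                                      CellType.SLOW, rng)
        assert daughter == (11, 10, 0)
        assert lat.grid[11, 10, 0] == 1   # daughter
        assert lat.grid[12, 10, 0] == 2   # shoved fast cell
        assert lat.grid[13, 10, 0] == 1   # shoved slow cell
        assert lat.n_cells == 4
        lat.audit()

    def test_diagonal_target_daughter_adjacent(self, rng):
        lat = build_lattice({(10, 10, 0): CellType.SLOW,
                             (11, 11, 0): CellType.FAST})
        before = occupied_multiset(lat)
        daughter = execute_horizontal(lat, (10, 10, 0), (12, 12, 0),
                                      CellType.SLOW, rng)
        assert daughter == (11, 11, 0)
        assert max(abs(daughter[0] - 10), abs(daughter[1] - 10)) == 1
        after = occupied_multiset(lat)
        before[1] = before.get(1, 0) + 1
        assert after == before
        lat.audit()

    def test_occupied_target_rejected(self, rng):
        lat = build_lattice({(10, 10, 0): CellType.SLOW,
                             (11, 10, 0): CellType.FAST})
        with pytest.raises(LatticeError):
            execute_horizontal(lat, (10, 10, 0), (11, 10, 0),
                               CellType.SLOW, rng)

    def test_cross_plane_target_rejected(self, rng):
        lat = build_lattice({(10, 10, 0): CellType.SLOW})
        with pytest.raises(LatticeError):
            execute_horizontal(lat, (10, 10, 0), (11, 10, 1),
                               CellType.SLOW, rng)

    def test_shove_path_is_chebyshev_line(self):
        path = shove_path((10, 10, 0), (13, 11, 0))
        assert path[-1] == (13, 11, 0)
        assert len(path) == 3
        prev = (10, 10, 0)
        for site in path:
            assert max(abs(site[0] - prev[0]), abs(site[1] - prev[1])) == 1
            assert site[2] == 0
            prev = site

    def test_random_divisions_conserve_cells(self, rng):
        """Property: after any division exactly one site is added and
        the multiset of pre-existing cell types is unchanged."""
        for _ in range(60):
            lat = random_lattice(rng, n_c=10, n_z=5,
                                 fill=rng.uniform(0.2, 0.95))
            if lat.n_cells == 0:
                continue
            i = int(rng.integers(lat.n_cells))
            mother = (int(lat.xs[i]), int(lat.ys[i]), int(lat.zs[i]))
            cell = CellType(int(lat.types[i]))
            before = occupied_multiset(lat)
            n_before = lat.n_cells
            plan = find_division_target(lat, mother, 3, rng)
            try:
                if plan.horizontal:
                    execute_horizontal(lat, mother, plan.target, cell, rng)
                else:
                    execute_vertical(lat, mother, cell)
            except ColumnOverflowError:
                continue
            assert lat.n_cells == n_before + 1
            before[int(cell)] = before.get(int(cell), 0) + 1
            assert occupied_multiset(lat) == before
            lat.audit()


class TestExecuteVertical:
    def test_no_stack_above(self):
        lat = build_lattice({(5, 5, 0): CellType.FAST})
        daughter = execute_vertical(lat, (5, 5, 0), CellType.FAST)
        assert daughter == (5, 5, 1)
        assert lat.grid[5, 5, 1] == 2
        lat.audit()

    def test_stack_shifts_up_one(self):
        """A 3-cell stack above the mother moves to z+2..z+4; the
        daughter takes z+1."""
        lat = build_lattice({(5, 5, 0): CellType.SLOW,
                             (5, 5, 1): CellType.FAST,
                             (5, 5, 2): CellType.SLOW,
                             (5, 5, 3): CellType.FAST})
        daughter = execute_vertical(lat, (5, 5, 0), CellType.SLOW)
        assert daughter == (5, 5, 1)
        assert [int(lat.grid[5, 5, z]) for z in range(6)] == \
            [1, 1, 2, 1, 2, 0]
        lat.audit()

    def test_gap_above_stack_preserved_beyond(self):
        """Only the contiguous stack shifts; cells past the first gap
        stay put."""
        lat = build_lattice({(5, 5, 0): CellType.SLOW,
                             (5, 5, 1): CellType.FAST,
                             (5, 5, 3): CellType.SLOW})  # gap at z=2
        execute_vertical(lat, (5, 5, 0), CellType.SLOW)
        assert [int(lat.grid[5, 5, z]) for z in range(5)] == [1, 1, 2, 1, 0]
        lat.audit()

    def test_full_column_overflows(self):
        lat = ColonyLattice(n_c=8, n_z=4)
        for z in range(4):
            lat.place((3, 3, z), CellType.SLOW)
        with pytest.raises(ColumnOverflowError):
            execute_vertical(lat, (3, 3, 0), CellType.SLOW)


class TestColonyLattice:
    def test_site_exclusivity_enforced(self):
        lat = ColonyLattice(10, 5)
        lat.place((1, 1, 0), CellType.SLOW)
        with pytest.raises(LatticeError):
            lat.place((1, 1, 0), CellType.FAST)

    def test_out_of_bounds_rejected(self):
        lat = ColonyLattice(10, 5)
        with pytest.raises(LatticeError):
            lat.place((0, 0, 5), CellType.SLOW)

    def test_counts_and_positions(self):
        lat = build_lattice({(0, 0, 0): CellType.SLOW,
                             (1, 0, 0): CellType.FAST,
                             (2, 0, 0): CellType.SLOW})
        assert lat.counts() == (2, 1)
        assert lat.positions().shape == (3, 3)

    def test_denominator_formula(self):
        lat = ColonyLattice(n_c=20, n_z=10, r_i=3)
        assert lat.denom[10, 10, 5] == 7 * 7 * 7 - 1
        assert lat.denom[0, 0, 0] == 4 * 4 * 4 - 1
        assert lat.denom[0, 10, 5] == 4 * 7 * 7 - 1
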