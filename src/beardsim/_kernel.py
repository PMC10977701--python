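"""Numba-accelerated inner loop of the colony simulation.

The functions here operate on raw arrays (occupancy grid, cached
neighborhood counts, flat cell coordinate arrays) and implement exactly
the division rules exposed piecewise by :mod:`beardsim.lattice`:
rate evaluation from local occupancy, nearest-empty-site search in the
mother's plane, horizontal shoving along a discretized line, and
vertical stacking.  The readable single-operation implementations in
``lattice.py`` are the reference semantics; the property tests assert
that this fused kernel agrees with them.

Cached counts: ``count_slow[x, y, z]`` holds the number of slow cells in
the cubic Chebyshev box of radius ``r_i`` centered at ``(x, y, z)``,
*including* the center site; the focal cell is subtracted at rate
evaluation.  Every placement or displacement updates the boxes it
touches, so occupancy lookups in the hot loop are O(1).
"""

from __future__ import annotations

import numpy as np
from numba import njit

# Step status codes.
STATUS_OK = 0
STATUS_OVERFLOW = 1  # a column hit the lattice ceiling
STATUS_CAPACITY = 2  # cell arrays exhausted (caller sized them too small)

SLOW = 1
FAST = 2


@njit(cache=True)
def seed_kernel_rng(seed):
    """Seed the RNG used inside jitted code (numba keeps its own stream)."""
    np.random.seed(seed)


@njit(cache=True, inline="always")
def _box_add(count, x, y, z, r, n_c, n_z, delta):
    x0 = max(0, x - r)
    x1 = min(n_c - 1, x + r)
    y0 = max(0, y - r)
    y1 = min(n_c - 1, y + r)
    z0 = max(0, z - r)
    z1 = min(n_z - 1, z + r)
    for xx in range(x0, x1 + 1):
        for yy in range(y0, y1 + 1):
            for zz in range(z0, z1 + 1):
                count[xx, yy, zz] += delta


@njit(cache=True)
def place_cell(grid, count_slow, count_fast, cell_index,
               xs, ys, zs, types, n, x, y, z, cell_type, r_i, n_c, n_z):
    """Add a new cell at an empty site; returns the new cell count."""
    grid[x, y, z] = cell_type
    cell_index[x, y, z] = n
    xs[n] = x
    ys[n] = y
    zs[n] = z
    types[n] = cell_type
    if cell_type == SLOW:
        _box_add(count_slow, x, y, z, r_i, n_c, n_z, 1)
    else:
        _box_add(count_fast, x, y, z, r_i, n_c, n_z, 1)
    return n + 1


@njit(cache=True)
def move_cell(grid, count_slow, count_fast, cell_index, xs, ys, zs,
              x0, y0, z0, x1, y1, z1, r_i, n_c, n_z):
    """Displace the occupant of (x0,y0,z0) to the empty site (x1,y1,z1)."""
    t = grid[x0, y0, z0]
    i = cell_index[x0, y0, z0]
    grid[x1, y1, z1] = t
    cell_index[x1, y1, z1] = i
    grid[x0, y0, z0] = 0
    cell_index[x0, y0, z0] = -1
    xs[i] = x1
    ys[i] = y1
    zs[i] = z1
    if t == SLOW:
        _box_add(count_slow, x0, y0, z0, r_i, n_c, n_z, -1)
        _box_add(count_slow, x1, y1, z1, r_i, n_c, n_z, 1)
    else:
        _box_add(count_fast, x0, y0, z0, r_i, n_c, n_z, -1)
        _box_add(count_fast, x1, y1, z1, r_i, n_c, n_z, 1)


@njit(cache=True)
def find_target(grid, x, y, z, r_d, n_c, u):
    """Nearest empty in-plane site within Chebyshev radius r_d of (x,y,z).

    Ties at the minimal distance are broken uniformly using ``u`` drawn
    from U[0,1).  Returns (found, tx, ty); found==0 means the whole
    in-lattice plane neighborhood is occupied (vertical fallback).
    """
    best = r_d + 1
    n_best = 0
    x0 = max(0, x - r_d)
    x1 = min(n_c - 1, x + r_d)
    y0 = max(0, y - r_d)
    y1 = min(n_c - 1, y + r_d)
    for xx in range(x0, x1 + 1):
        for yy in range(y0, y1 + 1):
            if xx == x and yy == y:
                continue
            if grid[xx, yy, z] != 0:
                continue
            d = max(abs(xx - x), abs(yy - y))
            if d < best:
                best = d
                n_best = 1
            elif d == best:
                n_best += 1
    if n_best == 0:
        return 0, -1, -1
    k = int(u * n_best)
    if k >= n_best:  # u could round up to exactly n_best only if u==1.0
        k = n_best - 1
    for xx in range(x0, x1 + 1):
        for yy in range(y0, y1 + 1):
            if xx == x and yy == y:
                continue
            if grid[xx, yy, z] != 0:
                continue
            if max(abs(xx - x), abs(yy - y)) == best:
                if k == 0:
                    return 1, xx, yy
                k -= 1
    return 0, -1, -1  # unreachable


@njit(cache=True, inline="always")
def _path_site(x, y, dx, dy, dist, k):
    """k-th site of the discretized straight line from mother toward target."""
    px = x + int(np.floor(k * dx / dist + 0.5))
    py = y + int(np.floor(k * dy / dist + 0.5))
    return px, py


@njit(cache=True)
def divide_horizontal(grid, count_slow, count_fast, cell_index,
                      xs, ys, zs, types, n,
                      x, y, z, tx, ty, cell_type, r_i, n_c, n_z):
    """Shove occupants one step outward along the mother→target line and
    place the daughter on the vacated mother-adjacent site."""
    dx = tx - x
    dy = ty - y
    dist = max(abs(dx), abs(dy))
    # Shift outward, far end first; the target site is empty by contract.
    for k in range(dist - 1, 0, -1):
        px, py = _path_site(x, y, dx, dy, dist, k)
        if grid[px, py, z] != 0:
            qx, qy = _path_site(x, y, dx, dy, dist, k + 1)
            move_cell(grid, count_slow, count_fast, cell_index, xs, ys, zs,
                      px, py, z, qx, qy, z, r_i, n_c, n_z)
    px, py = _path_site(x, y, dx, dy, dist, 1)
    return place_cell(grid, count_slow, count_fast, cell_index,
                      xs, ys, zs, types, n, px, py, z, cell_type,
                      r_i, n_c, n_z)


@njit(cache=True)
def divide_vertical(grid, count_slow, count_fast, cell_index,
                    xs, ys, zs, types, n,
                    x, y, z, cell_type, r_i, n_c, n_z):
    """Push the contiguous stack above the mother up one site and place
    the daughter directly above her.  Returns (new_n, status)."""
    z_empty = -1
    for zz in range(z + 1, n_z):
        if grid[x, y, zz] == 0:
            z_empty = zz
            break
    if z_empty < 0:
        return n, STATUS_OVERFLOW
    for zz in range(z_empty - 1, z, -1):
        move_cell(grid, count_slow, count_fast, cell_index, xs, ys, zs,
                  x, y, zz, x, y, zz + 1, r_i, n_c, n_z)
    n = place_cell(grid, count_slow, count_fast, cell_index,
                   xs, ys, zs, types, n, x, y, z + 1, cell_type,
                   r_i, n_c, n_z)
    return n, STATUS_OK


@njit(cache=True)
def step(grid, count_slow, count_fast, denom, cell_index,
         xs, ys, zs, types, n,
         r_s0, r_f0, r_ss, r_sf, r_fs, r_ff, chi, dt,
         r_i, r_d, n_c, n_z):
    """One Monte Carlo sweep over the cells present at its start.

    Cells are visited in a fresh uniform shuffle; each divides with
    probability rate*dt where the rate is evaluated on the current
    (mid-sweep) lattice state.  Daughters do not divide until the next
    sweep.  Returns (new_n, status).
    """
    n_start = n
    order = np.empty(n_start, dtype=np.int64)
    for i in range(n_start):
        order[i] = i
    for i in range(n_start - 1, 0, -1):  # Fisher-Yates
        j = np.random.randint(0, i + 1)
        tmp = order[i]
        order[i] = order[j]
        order[j] = tmp

    capacity = xs.shape[0]
    for k in range(n_start):
        i = order[k]
        x = xs[i]
        y = ys[i]
        z = zs[i]
        t = types[i]
        n_s = count_slow[x, y, z]
        n_f = count_fast[x, y, z]
        if t == SLOW:
            n_s -= 1
        else:
            n_f -= 1
        den = denom[x, y, z]
        phi_s = n_s / den
        phi_f = n_f / den
        crowd = 1.0 - chi * (phi_s + phi_f)
        if t == SLOW:
            rate = (r_s0 + r_sf * phi_f + r_ss * phi_s) * crowd
        else:
            rate = (r_f0 + r_fs * phi_s + r_ff * phi_f) * crowd
        if rate <= 0.0:
            continue
        if np.random.random() >= rate * dt:
            continue
        if n >= capacity:
            return n, STATUS_CAPACITY
        found, tx, ty = find_target(grid, x, y, z, r_d, n_c,
                                    np.random.random())
        if found == 1:
            n = divide_horizontal(grid, count_slow, count_fast, cell_index,
                                  xs, ys, zs, types, n, x, y, z, tx, ty, t,
                                  r_i, n_c, n_z)
        else:
            n, status = divide_vertical(grid, count_slow, count_fast,
                                        cell_index, xs, ys, zs, types, n,
                                        x, y, z, t, r_i, n_c, n_z)
            if status != STATUS_OK:
                return n, status
    return n, STATUS_OK
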