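"""Inoculation, the Monte Carlo division loop, and stage capture.

A run starts from a dilute inoculum in a centered ``d x d`` square of
the bottom layer and repeats discrete sweeps: every cell present at the
start of a sweep divides with probability ``rate * dt``, where the rate
is evaluated from its current neighborhood (mid-sweep state included).
Two snapshots are captured:

* **sparse** — the first time a bottom-layer cell touches the lateral
  boundary of the grid, while the community is still spread out;
* **dense** — when the colony reaches the stopping threshold ``T``
  cells (the sweep in progress completes first).

Runs are deterministic given the configuration and seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import _kernel
from .lattice import ColonyLattice
from .model import CellType, InteractionParams

#: Extra cell-array headroom beyond T for divisions in the final sweep.
_CAPACITY_SLACK = 8192


class SimulationError(Exception):
    pass


class StallError(SimulationError):
    """No division occurred for the configured number of sweeps."""


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of a single run; defaults are the standard study setup.

    ``dt * max rate`` must stay well below 1 so that ``rate * dt`` is a
    valid per-sweep division probability.
    """

    params: InteractionParams = field(default_factory=InteractionParams)
    n_c: int = 50           # lateral lattice extent (sites)
    n_z: int = 100          # lattice height (sites)
    t_stop: int = 50_000    # cell-count stopping threshold T
    d: int = 15             # inoculation square side
    f: float = 0.05         # inoculum fill fraction of the square
    f_s: float = 0.5        # slow fraction of the inoculum
    r_i: int = 3            # interaction radius
    r_d: int = 3            # displacement radius
    dt: float = 0.1         # sweep time step
    seed: int = 0
    stall_cap: int = 1_000_000  # sweeps without division before aborting

    def __post_init__(self):
        if self.d > self.n_c:
            raise ValueError("inoculation square must fit the lattice (d <= n_c)")
        if not (0 <= self.f <= 1):
            raise ValueError("f must be in [0, 1]")
        if not (0 <= self.f_s <= 1):
            raise ValueError("f_s must be in [0, 1]")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.r_i < 1 or self.r_d < 1:
            raise ValueError("radii must be >= 1")
        if self.t_stop < 1:
            raise ValueError("t_stop must be >= 1")
        # rate*dt must be a probability; bound the rate by its maximum
        # over phi in [0,1] for both strains.
        p = self.params
        from .model import max_growth_rate
        r_bound = max(max_growth_rate(p.r_s0, max(p.r_ss, p.r_sf), p.chi)[0],
                      max_growth_rate(p.r_f0, max(p.r_ff, p.r_fs), p.chi)[0])
        if r_bound * self.dt > 1:
            raise ValueError(
                f"dt * max possible rate = {r_bound * self.dt:.3g} exceeds 1")

    def replace(self, **kw) -> "SimulationConfig":
        return dataclasses.replace(self, **kw)


@dataclass(frozen=True)
class Snapshot:
    """A frozen copy of the colony at a measurement stage."""

    stage: str                  # "sparse" or "dense"
    grid: np.ndarray            # int8 (n_c, n_c, n_z) site states
    sim_time: float             # sweeps elapsed * dt
    n_cells: int
    n_slow: int
    n_fast: int

    def coordinates(self) -> np.ndarray:
        """(n_cells, 4) int array of (x, y, z, type)."""
        xs, ys, zs = np.nonzero(self.grid)
        t = self.grid[xs, ys, zs].astype(int)
        return np.column_stack((xs, ys, zs, t))


@dataclass(frozen=True)
class RunResult:
    """Snapshots plus how the run ended."""

    sparse: Optional[Snapshot]
    dense: Snapshot
    overflowed: bool            # hit the lattice ceiling before T
    n_steps: int
    divisions: int


def take_snapshot(lat: ColonyLattice, stage: str, sim_time: float) -> Snapshot:
    n_slow, n_fast = lat.counts()
    return Snapshot(stage=stage, grid=lat.grid.copy(), sim_time=sim_time,
                    n_cells=lat.n_cells, n_slow=n_slow, n_fast=n_fast)


def inoculate(cfg: SimulationConfig,
              rng: np.random.Generator) -> ColonyLattice:
    """Seed the lattice with a dilute inoculum.

    ``n0 = round(f * d^2)`` distinct sites are drawn uniformly without
    replacement from the centered ``d x d`` square of the bottom layer;
    ``round(f_s * n0)`` of them (chosen uniformly) become slow cells and
    the rest fast.  Rounding is half-up so replicate composition is
    deterministic.
    """
    n0 = _round_half_up(cfg.f * cfg.d * cfg.d)
    if n0 == 0:
        raise SimulationError("empty inoculum: f * d^2 rounds to zero cells")
    capacity = min(cfg.t_stop + _CAPACITY_SLACK, cfg.n_c * cfg.n_c * cfg.n_z)
    lat = ColonyLattice(n_c=cfg.n_c, n_z=cfg.n_z, r_i=cfg.r_i,
                        capacity=capacity)
    offset = (cfg.n_c - cfg.d) // 2
    flat = rng.choice(cfg.d * cfg.d, size=n0, replace=False)
    n_slow = _round_half_up(cfg.f_s * n0)
    which_slow = np.zeros(n0, dtype=bool)
    which_slow[rng.choice(n0, size=n_slow, replace=False)] = True
    for k in range(n0):
        x = offset + int(flat[k]) // cfg.d
        y = offset + int(flat[k]) % cfg.d
        cell = CellType.SLOW if which_slow[k] else CellType.FAST
        lat.place((x, y, 0), cell)
    return lat


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def step(lat: ColonyLattice, cfg: SimulationConfig,
         rng: np.random.Generator) -> int:
    """One Monte Carlo sweep; returns the number of divisions.

    Cells present at the start of the sweep are visited in a fresh
    uniform shuffle; daughters born during the sweep wait until the
    next one.  Raises :class:`ColumnOverflowError` via the run loop's
    status handling if a column hits the ceiling.
    """
    if lat.n_cells == 0:
        raise SimulationError("cannot step an empty lattice")
    n, status = _step_raw(lat, cfg, rng)
    divisions = n - lat.n_cells
    lat.n_cells = n
    if status == _kernel.STATUS_OVERFLOW:
        from .lattice import ColumnOverflowError
        raise ColumnOverflowError("a column reached the lattice ceiling")
    if status == _kernel.STATUS_CAPACITY:
        raise SimulationError("cell arrays exhausted during a sweep")
    return divisions


def _step_raw(lat: ColonyLattice, cfg: SimulationConfig,
              rng: np.random.Generator) -> tuple[int, int]:
    # numba keeps its own RNG stream; derive its per-sweep seed from the
    # run generator so the whole trajectory is a function of cfg.seed.
    _kernel.seed_kernel_rng(int(rng.integers(0, 2**31 - 1)))
    p = cfg.params
    return _kernel.step(
        lat.grid, lat.count_slow, lat.count_fast, lat.denom, lat.cell_index,
        lat.xs, lat.ys, lat.zs, lat.types, lat.n_cells,
        p.r_s0, p.r_f0, p.r_ss, p.r_sf, p.r_fs, p.r_ff, p.chi, cfg.dt,
        cfg.r_i, cfg.r_d, cfg.n_c, cfg.n_z)


def _touches_edge(lat: ColonyLattice) -> bool:
    g = lat.grid
    return bool(g[0, :, 0].any() or g[-1, :, 0].any()
                or g[:, 0, 0].any() or g[:, -1, 0].any())


def run(cfg: SimulationConfig, log=None) -> RunResult:
    """Run one colony to its stopping point.

    Returns the sparse and dense snapshots.  If a column overflows the
    lattice ceiling before the threshold is reached, the partial state
    is returned with ``overflowed=True``.  A colony that stops dividing
    entirely raises :class:`StallError` after ``cfg.stall_cap`` sweeps.

    ``log``, if given, receives plain-text progress lines: the seed,
    per-1,000-cell growth milestones, stage captures, and the
    termination reason.
    """
    rng = np.random.default_rng(cfg.seed)
    if log:
        log(f"run start: seed={cfg.seed} n_c={cfg.n_c} n_z={cfg.n_z} "
            f"t_stop={cfg.t_stop} f_s={cfg.f_s}")
    next_milestone = 1000
    lat = inoculate(cfg, rng)
    sparse: Optional[Snapshot] = None
    n_steps = 0
    divisions = 0
    overflowed = False
    idle = 0
    if _touches_edge(lat):  # degenerate d ~ n_c inocula
        sparse = take_snapshot(lat, "sparse", 0.0)
    while lat.n_cells < cfg.t_stop:
        n, status = _step_raw(lat, cfg, rng)
        d = n - lat.n_cells
        lat.n_cells = n
        n_steps += 1
        divisions += d
        idle = 0 if d else idle + 1
        if status == _kernel.STATUS_OVERFLOW:
            overflowed = True
            break
        if status == _kernel.STATUS_CAPACITY:
            raise SimulationError("cell arrays exhausted during a sweep")
        if sparse is None and _touches_edge(lat):
            sparse = take_snapshot(lat, "sparse", n_steps * cfg.dt)
            if log:
                log(f"sparse stage captured: n={sparse.n_cells} "
                    f"t={sparse.sim_time:g}")
        if log and lat.n_cells >= next_milestone:
            while next_milestone <= lat.n_cells:
                next_milestone += 1000
            log(f"n={lat.n_cells} t={n_steps * cfg.dt:g}")
        if idle >= cfg.stall_cap:
            raise StallError(
                f"no division in {idle} consecutive sweeps (all rates zero?)")
    dense = take_snapshot(lat, "dense", n_steps * cfg.dt)
    if log:
        reason = "lattice ceiling reached" if overflowed \
            else "cell-count threshold reached"
        log(f"dense stage captured: n={dense.n_cells} "
            f"t={dense.sim_time:g} ({reason})")
    return RunResult(sparse=sparse, dense=dense, overflowed=overflowed,
                     n_steps=n_steps, divisions=divisions)
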