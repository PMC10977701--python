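"""Colony-level statistics and replicate aggregation.

Per-snapshot measurements: strain proportions in the whole colony, on
the colony surface (the topmost cell of every occupied (x, y) column),
and the occupied fraction of the bottom layer.  Replicates of a sweep
cell are aggregated to means with standard errors, and pairs of
aggregates are compared as differences with errors propagated in
quadrature.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .model import CellType
from .simulate import Snapshot

#: Grouping key of a sweep cell.
GROUP_KEY = ["scenario", "r", "f_s", "stage"]

#: Column order of the per-replicate records CSV.
RECORD_COLUMNS = ["scenario", "r", "f_s", "replicate", "seed", "stage",
                  "n_cells", "prop_slow_total", "prop_slow_surface",
                  "bottom_fill", "sim_time"]


class MeasurementError(Exception):
    pass


@dataclass(frozen=True)
class SummaryRecord:
    """One replicate's measurements at one stage (a CSV row)."""

    scenario: str
    r: float
    f_s: float
    replicate: int
    seed: int
    stage: str
    n_cells: int
    prop_slow_total: float
    prop_slow_surface: float
    bottom_fill: float
    sim_time: float


@dataclass(frozen=True)
class SweepSummary:
    """Mean and standard error over the replicates of one sweep cell."""

    scenario: str
    r: float
    f_s: float
    stage: str
    n: int
    mean_prop_slow_total: float
    sem_prop_slow_total: float
    mean_prop_slow_surface: float
    sem_prop_slow_surface: float
    mean_bottom_fill: float
    sem_bottom_fill: float

    @property
    def key(self) -> tuple:
        return (self.scenario, self.r, self.f_s, self.stage)


@dataclass(frozen=True)
class BenefitEstimate:
    """A difference of group means with SEMs propagated in quadrature."""

    r: float
    f_s: float
    stage: str
    difference: float
    sem: float


def total_proportions(snap: Snapshot) -> tuple[float, float]:
    """(prop_slow, prop_fast) over the whole colony."""
    if snap.n_cells == 0:
        raise MeasurementError("proportions undefined for an empty colony")
    return snap.n_slow / snap.n_cells, snap.n_fast / snap.n_cells


def surface_cells(snap: Snapshot) -> np.ndarray:
    """Types of the topmost cell of every occupied (x, y) column.

    Scanning from the top layer downward, the first cell met in each
    column is the surface cell; empty columns contribute nothing.
    """
    occupied = snap.grid != 0
    any_cell = occupied.any(axis=2)
    # highest occupied z per column: argmax on the reversed z axis
    n_z = snap.grid.shape[2]
    top = n_z - 1 - np.argmax(occupied[:, :, ::-1], axis=2)
    xs, ys = np.nonzero(any_cell)
    return snap.grid[xs, ys, top[xs, ys]]


def surface_proportions(snap: Snapshot) -> tuple[float, float]:
    """(prop_slow, prop_fast) among surface cells only."""
    if snap.n_cells == 0:
        raise MeasurementError("proportions undefined for an empty colony")
    tops = surface_cells(snap)
    n_slow = int(np.count_nonzero(tops == int(CellType.SLOW)))
    return n_slow / tops.size, 1.0 - n_slow / tops.size


def bottom_fill(snap: Snapshot) -> float:
    """Occupied fraction of the z = 0 plane."""
    base = snap.grid[:, :, 0]
    return float(np.count_nonzero(base)) / base.size


def record_from_snapshot(snap: Snapshot, *, scenario: str, r: float,
                         f_s: float, replicate: int,
                         seed: int) -> SummaryRecord:
    """Measure one snapshot into a CSV-ready record."""
    prop_slow, _ = total_proportions(snap)
    prop_slow_surface, _ = surface_proportions(snap)
    return SummaryRecord(
        scenario=scenario, r=r, f_s=f_s, replicate=replicate, seed=seed,
        stage=snap.stage, n_cells=snap.n_cells,
        prop_slow_total=prop_slow, prop_slow_surface=prop_slow_surface,
        bottom_fill=bottom_fill(snap), sim_time=snap.sim_time)


def records_to_frame(records: Iterable[SummaryRecord]) -> pd.DataFrame:
    df = pd.DataFrame([asdict(rec) for rec in records])
    return df[RECORD_COLUMNS]


def summarize(records: Sequence[SummaryRecord],
              expected_n: Optional[int] = None) -> list[SweepSummary]:
    """Group records by (scenario, r, f_s, stage) and aggregate.

    SEM uses the n-1 sample standard deviation over n replicates.
    Singleton groups (SEM undefined) and, if ``expected_n`` is given,
    groups of any other size raise :class:`MeasurementError`.
    """
    if not records:
        return []
    df = records_to_frame(records)
    out: list[SweepSummary] = []
    for key, g in df.groupby(GROUP_KEY, sort=True):
        n = len(g)
        if n < 2:
            raise MeasurementError(f"group {key}: SEM undefined for n={n}")
        if expected_n is not None and n != expected_n:
            raise MeasurementError(
                f"group {key}: expected {expected_n} replicates, found {n}")
        stats = {}
        for col in ("prop_slow_total", "prop_slow_surface", "bottom_fill"):
            v = g[col].to_numpy(dtype=float)
            stats[f"mean_{col}"] = float(v.mean())
            stats[f"sem_{col}"] = float(v.std(ddof=1) / np.sqrt(n))
        out.append(SweepSummary(scenario=key[0], r=float(key[1]),
                                f_s=float(key[2]), stage=key[3], n=n, **stats))
    return out


def summaries_to_frame(summaries: Iterable[SweepSummary]) -> pd.DataFrame:
    return pd.DataFrame([asdict(s) for s in summaries])


def benefit(summary_a: SweepSummary, summary_b: SweepSummary,
            column: str = "prop_slow_total") -> BenefitEstimate:
    """Difference of group means (a minus b) at matching (r, f_s, stage).

    Typical use: greenbeard minus obligate final slow proportion — a
    positive value means the recognizing cooperator ended at a higher
    frequency than the indiscriminate one.
    """
    if (summary_a.r, summary_a.f_s, summary_a.stage) != (
            summary_b.r, summary_b.f_s, summary_b.stage):
        raise MeasurementError(
            f"mismatched keys: {summary_a.key} vs {summary_b.key}")
    mean_a = getattr(summary_a, f"mean_{column}")
    mean_b = getattr(summary_b, f"mean_{column}")
    sem_a = getattr(summary_a, f"sem_{column}")
    sem_b = getattr(summary_b, f"sem_{column}")
    return BenefitEstimate(r=summary_a.r, f_s=summary_a.f_s,
                           stage=summary_a.stage,
                           difference=mean_a - mean_b,
                           sem=float(np.hypot(sem_a, sem_b)))
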