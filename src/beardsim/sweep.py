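"""Sweep orchestration over scenarios x cooperation strength x inoculum
composition, with CSV output and the analytic x-axis mapping.

Every run in a sweep gets ``seed = base_seed + sequential index`` over
the Cartesian product, so any single replicate can be regenerated
bit-identically from the records CSV alone.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .measure import (SummaryRecord, SweepSummary, record_from_snapshot,
                      records_to_frame, summaries_to_frame, summarize)
from .model import (DEFAULT_CHI, DEFAULT_R_F0, DEFAULT_R_S0, STUDY_R_VALUES,
                    Scenario, ScenarioSpec, max_growth_rate, scenario_params)
from .simulate import RunResult, SimulationConfig, run

#: Inoculum slow-fractions used in the competition sweeps.
STUDY_F_S_VALUES = (0.1, 0.3, 0.5, 0.7)
#: Extra starting ratio used when both strains cooperate.
STUDY_F_S_EXTENDED = STUDY_F_S_VALUES + (0.9,)


@dataclass(frozen=True)
class SweepSpec:
    """The grid of runs to execute.

    ``r = 0`` entries are run as BASELINE regardless of scenario, so a
    sweep that includes 0 in ``r_values`` carries its own no-cooperation
    reference point.
    """

    scenarios: Sequence[Scenario] = (Scenario.OBLIGATE, Scenario.GREENBEARD)
    r_values: Sequence[float] = (0.0,) + STUDY_R_VALUES
    f_s_values: Sequence[float] = STUDY_F_S_VALUES
    n_replicates: int = 20
    base_seed: int = 0

    def cells(self) -> list[tuple[Scenario, float, float]]:
        """The (scenario, r, f_s) grid, baseline points deduplicated."""
        out = []
        seen = set()
        for f_s in self.f_s_values:
            for scen in self.scenarios:
                for r in self.r_values:
                    key = (Scenario.BASELINE if r == 0 else scen, r, f_s)
                    if key not in seen:
                        seen.add(key)
                        out.append(key)
        return out

    @property
    def n_runs(self) -> int:
        return len(self.cells()) * self.n_replicates


def config_for(scenario: Scenario, r: float, f_s: float, seed: int,
               defaults: Optional[SimulationConfig] = None,
               r_s0: float = DEFAULT_R_S0, r_f0: float = DEFAULT_R_F0,
               chi: float = DEFAULT_CHI) -> SimulationConfig:
    """A run configuration for one sweep cell."""
    if defaults is None:
        defaults = SimulationConfig()
    params = scenario_params(ScenarioSpec(scenario, r), r_s0, r_f0, chi)
    return defaults.replace(params=params, f_s=f_s, seed=seed)


def run_cell(scenario: Scenario, r: float, f_s: float, replicate: int,
             seed: int, defaults: Optional[SimulationConfig] = None,
             ) -> tuple[list[SummaryRecord], RunResult]:
    """Run one replicate and measure both stages."""
    cfg = config_for(scenario, r, f_s, seed, defaults)
    result = run(cfg)
    records = []
    for snap in (result.sparse, result.dense):
        if snap is not None:
            records.append(record_from_snapshot(
                snap, scenario=scenario.value, r=r, f_s=f_s,
                replicate=replicate, seed=seed))
    return records, result


def run_sweep(spec: SweepSpec,
              defaults: Optional[SimulationConfig] = None,
              out_dir: Optional[Path] = None,
              export_first_replicate: bool = False,
              progress: bool = False,
              ) -> tuple[list[SummaryRecord], list[SweepSummary]]:
    """Execute every (scenario, r, f_s, replicate) run of the spec.

    Writes ``records.csv`` (one row per run per stage) and
    ``summaries.csv`` (one row per group) into ``out_dir`` when given;
    optionally also the first replicate's dense-stage coordinates per
    cell, the substrate for 3-D renderings.
    """
    cells = spec.cells()
    iterator = enumerate(cells)
    if progress:
        from tqdm import tqdm
        iterator = enumerate(tqdm(cells, desc="sweep cells"))
    records: list[SummaryRecord] = []
    for i, (scenario, r, f_s) in iterator:
        for k in range(spec.n_replicates):
            seed = spec.base_seed + i * spec.n_replicates + k
            cell_records, result = run_cell(scenario, r, f_s, k, seed,
                                            defaults)
            records.extend(cell_records)
            if export_first_replicate and k == 0 and out_dir is not None:
                name = f"colony_{scenario.value}_r{r:g}_fs{f_s:g}.csv"
                export_coordinates(result.dense, Path(out_dir) / name)
    summaries = summarize(records)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        records_to_frame(records).to_csv(out_dir / "records.csv", index=False)
        summaries_to_frame(summaries).to_csv(out_dir / "summaries.csv",
                                             index=False)
    return records, summaries


def export_coordinates(snap, path: Path) -> None:
    """Write a snapshot as an x,y,z,type CSV (type in {S, F})."""
    coords = snap.coordinates()
    df = pd.DataFrame(coords, columns=["x", "y", "z", "type"])
    df["type"] = df["type"].map({1: "S", 2: "F"})
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def analytics_report(r_s0: float = DEFAULT_R_S0, r_f0: float = DEFAULT_R_F0,
                     chi: float = DEFAULT_CHI,
                     r_values: Sequence[float] = (0.0,) + STUDY_R_VALUES,
                     ) -> pd.DataFrame:
    """Tabulate the maximum slow-strain growth rate per cooperation
    strength — the x-axis mapping used to present sweep results."""
    rows = []
    for r in r_values:
        r_max, phi_star = max_growth_rate(r_s0, r, chi)
        rows.append({"r": r, "r_max": r_max, "phi_star": phi_star,
                     "exceeds_fast_baseline": r_max > r_f0})
    return pd.DataFrame(rows)
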