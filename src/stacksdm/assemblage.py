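"""Richness stacking and range-change dynamics by guild and habitat.

Species richness is the per-cell sum of binary presence maps over a
species group. Range change compares each future scenario's projected
area against the current projection: change = (future - current) /
current, with area = presence cells x cell area (100 km^2 at the 10 km
default). Loss/gain censuses bin species at nested magnitude thresholds
(20%, 50%, 90%, 100%), mirroring the usual presentation of projected
range dynamics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd

from .ensemble import ScenarioMapSet


@dataclass
class RichnessMap:
    scenario_id: str
    counts: np.ndarray
    group_size: int

    @property
    def percentage(self) -> np.ndarray:
        return 100.0 * self.counts / self.group_size


def stack_richness(binary_maps: Sequence[np.ndarray],
                   scenario_id: str) -> RichnessMap:
    """Per-cell species count from a group of binary maps."""
    if len(binary_maps) == 0:
        raise ValueError("empty species group")
    shape = np.asarray(binary_maps[0]).shape
    total = np.zeros(shape, dtype=int)
    for m in binary_maps:
        m = np.asarray(m)
        if m.shape != shape:
            raise ValueError("binary maps are not on a common grid")
        total += (m > 0).astype(int)
    return RichnessMap(scenario_id=scenario_id, counts=total,
                       group_size=len(binary_maps))


def range_change(map_set: ScenarioMapSet,
                 cell_area_km2: float = 100.0) -> pd.DataFrame:
    """Per-scenario projected area and fractional change vs current.

    A species must have nonzero current area (small ranges are excluded
    upstream). A future change of -1 means total loss of suitable
    habitat within the analysis extent.
    """
    cur = int(np.asarray(map_set.binary["current"]).sum())
    if cur == 0:
        raise ValueError(
            f"{map_set.species_id}: zero current area (should have been "
            "excluded by the small-range filter)")
    rows = []
    cur_area = cur * cell_area_km2
    for sid, bmap in map_set.binary.items():
        cells = int(np.asarray(bmap).sum())
        area = cells * cell_area_km2
        rows.append({
            "species": map_set.species_id,
            "scenario": sid,
            "current_area_km2": cur_area,
            "area_km2": area,
            "change_fraction": (area - cur_area) / cur_area,
        })
    return pd.DataFrame(rows)


def build_range_change_table(map_sets: Sequence[ScenarioMapSet],
                             species_meta: Dict[str, tuple],
                             cell_area_km2: float = 100.0) -> pd.DataFrame:
    """Concatenate per-species range changes with guild/habitat labels."""
    frames = []
    for ms in map_sets:
        df = range_change(ms, cell_area_km2)
        guild, habitat = species_meta[ms.species_id]
        df["guild"] = guild
        df["habitat"] = habitat
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


LOSS_GAIN_THRESHOLDS = (0.20, 0.50, 0.90, 1.00)


def loss_gain_census(table: pd.DataFrame,
                     thresholds: Sequence[float] = LOSS_GAIN_THRESHOLDS
                     ) -> pd.DataFrame:
    """Counts of species losing/gaining at least each threshold fraction.

    A species is counted in every bin it meets, so bins are nested
    (every >= 90% loser is also a >= 50% and >= 20% loser). The 100%
    loss bin is the total-loss category: no suitable habitat remains.
    Counted separately per guild x habitat x future scenario.
    """
    fut = table[table["scenario"] != "current"]
    rows = []
    for (guild, habitat, scen), grp in fut.groupby(
            ["guild", "habitat", "scenario"]):
        ch = grp["change_fraction"].to_numpy()
        for t in thresholds:
            rows.append({
                "guild": guild, "habitat": habitat, "scenario": scen,
                "threshold": t,
                "n_loss": int((ch <= -t).sum()),
                "n_gain": int((ch >= t).sum()),
                "n_species": len(grp),
            })
    return pd.DataFrame(rows)


def guild_area_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Mean, median and quartiles of projected area per group.

    Grouped by guild x habitat x scenario; quartiles use linear
    interpolation. Empty groups are simply absent from the output.
    """
    rows = []
    for (guild, habitat, scen), grp in table.groupby(
            ["guild", "habitat", "scenario"]):
        a = grp["area_km2"].to_numpy()
        rows.append({
            "guild": guild, "habitat": habitat, "scenario": scen,
            "n_species": len(a),
            "mean_area_km2": float(a.mean()),
            "median_area_km2": float(np.median(a)),
            "q25_area_km2": float(np.quantile(a, 0.25)),
            "q75_area_km2": float(np.quantile(a, 0.75)),
        })
    return pd.DataFrame(rows)
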