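"""Protected-area effectiveness and climatically stable area analysis.

Two conservation products are derived from the stacked projections:

* A protected-area (PA) report: for each PA block, how many of the
  species currently projected inside it are retained, lost or gained
  under each future scenario; percent loss is relative to current
  richness assuming no turnover.
* A stable-area classification: grid cells that hold at least X% of the
  species of EVERY trophic guild (X swept 20..80% in 10% steps) in at
  least 6 of the 7 climate scenarios are "climatically stable"; stable
  cells are partitioned into protected, deforested, or intact but
  unprotected (precedence protected > deforested > intact).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

CLASS_PROTECTED = 1
CLASS_INTACT_UNPROTECTED = 2
CLASS_DEFORESTED = 3

DEFAULT_GUILD_THRESHOLDS = tuple(range(20, 81, 10))


def pa_effectiveness(binary_maps: Dict[str, Dict[str, np.ndarray]],
                     pa_block_ids: np.ndarray) -> pd.DataFrame:
    """Species retention/loss/turnover per PA block and scenario.

    ``binary_maps`` maps species -> scenario -> binary map. A species is
    present in a block under a scenario iff at least one of its presence
    cells falls inside the block. Lost = present now, absent in the
    future; gained (turnover) = absent now, present in the future;
    percent lost is on the no-turnover basis (lost / current x 100).
    """
    ids = np.asarray(pa_block_ids)
    blocks = sorted(int(b) for b in np.unique(ids) if b != 0)
    if not blocks:
        raise ValueError("no PA blocks in the id grid")
    scenarios = None
    presence: Dict[Tuple[str, str], set] = {}
    for sp, per_scen in binary_maps.items():
        if scenarios is None:
            scenarios = list(per_scen)
        for sid, bmap in per_scen.items():
            bmap = np.asarray(bmap) > 0
            present_blocks = set(
                int(b) for b in np.unique(ids[bmap]) if b != 0)
            presence[(sp, sid)] = present_blocks
    rows = []
    future = [s for s in scenarios if s != "current"]
    for b in blocks:
        if not np.any(ids == b):
            raise ValueError(f"PA block {b} is empty")
        current_sp = {sp for sp in binary_maps
                      if b in presence[(sp, "current")]}
        for sid in future:
            future_sp = {sp for sp in binary_maps if b in presence[(sp, sid)]}
            lost = current_sp - future_sp
            retained = current_sp & future_sp
            gained = future_sp - current_sp
            n_cur = len(current_sp)
            rows.append({
                "pa_block": b, "scenario": sid,
                "current_richness": n_cur,
                "retained": len(retained),
                "lost": len(lost),
                "gained": len(gained),
                "percent_lost": (100.0 * len(lost) / n_cur
                                 if n_cur else float("nan")),
            })
    return pd.DataFrame(rows)


def guild_threshold_mask(guild_richness: Dict[str, np.ndarray],
                         guild_totals: Dict[str, int],
                         x_percent: float) -> np.ndarray:
    """Cells holding at least X% of every guild's species.

    The required count per guild is ceil(X% of the guild total), so the
    integer richness needed is conservative. X = 0 qualifies every cell.
    """
    shape = next(iter(guild_richness.values())).shape
    mask = np.ones(shape, dtype=bool)
    for g, rich in guild_richness.items():
        total = guild_totals[g]
        if total <= 0:
            raise ValueError(f"guild {g!r} has no species")
        need = math.ceil(x_percent / 100.0 * total)
        mask &= np.asarray(rich) >= need
    return mask


def stability_map(scenario_masks: Sequence[np.ndarray],
                  n_scenarios: int = 7,
                  min_coincidence: int = 6
                  ) -> Tuple[np.ndarray, np.ndarray]:
    """Scenario coincidence counts and the stability mask.

    A cell is climatically stable iff it qualifies in at least
    ``min_coincidence`` of the ``n_scenarios`` scenarios (6 of 7 by
    default).
    """
    if len(scenario_masks) != n_scenarios:
        raise ValueError(
            f"expected {n_scenarios} scenario masks, got "
            f"{len(scenario_masks)}")
    counts = np.zeros(np.asarray(scenario_masks[0]).shape, dtype=int)
    for m in scenario_masks:
        counts += np.asarray(m).astype(int)
    return counts, counts >= min_coincidence


def classify_stable_cells(stable_mask: np.ndarray, pa_mask: np.ndarray,
                          deforest_mask: np.ndarray,
                          cell_area_km2: float = 100.0
                          ) -> Tuple[np.ndarray, Dict[str, float]]:
    """Partition stable cells into protected / deforested / intact.

    Precedence protected > deforested > intact resolves mask overlaps.
    Returns a classification map (0 = not stable) and an exhaustive,
    disjoint area accounting in km^2.
    """
    stable = np.asarray(stable_mask, dtype=bool)
    pa = np.asarray(pa_mask, dtype=bool)
    defo = np.asarray(deforest_mask, dtype=bool)
    if not (stable.shape == pa.shape == defo.shape):
        raise ValueError("masks are not on a common grid")
    cls = np.zeros(stable.shape, dtype=np.uint8)
    cls[stable & pa] = CLASS_PROTECTED
    cls[stable & ~pa & defo] = CLASS_DEFORESTED
    cls[stable & ~pa & ~defo] = CLASS_INTACT_UNPROTECTED
    areas = {
        "stable_total_km2": float(stable.sum()) * cell_area_km2,
        "protected_km2": float((cls == CLASS_PROTECTED).sum()) * cell_area_km2,
        "intact_unprotected_km2":
            float((cls == CLASS_INTACT_UNPROTECTED).sum()) * cell_area_km2,
        "deforested_km2":
            float((cls == CLASS_DEFORESTED).sum()) * cell_area_km2,
    }
    return cls, areas


def downscale_deforestation(fine_mask: np.ndarray,
                            factor: int,
                            rule_fraction: float = 0.5) -> np.ndarray:
    """Majority-rule aggregation of a fine deforestation mask.

    The fine grid must nest exactly ``factor`` x ``factor`` fine cells
    per coarse cell; a coarse cell is flagged deforested iff the
    deforested fraction of its fine cells is >= ``rule_fraction``.
    """
    fine = np.asarray(fine_mask, dtype=bool)
    nr, nc = fine.shape
    if factor < 1 or nr % factor or nc % factor:
        raise ValueError(
            f"fine grid {fine.shape} does not nest with factor {factor}")
    frac = fine.reshape(nr // factor, factor, nc // factor, factor)
    frac = frac.mean(axis=(1, 3))
    return frac >= rule_fraction


@dataclass
class StableAreaResult:
    """Stable-area sweep over guild thresholds."""
    thresholds: List[int]
    stable_area_km2: List[float]
    class_areas: List[Dict[str, float]]
    classification: Dict[int, np.ndarray] = field(default_factory=dict)

    def as_frame(self) -> pd.DataFrame:
        rows = []
        for t, a, cl in zip(self.thresholds, self.stable_area_km2,
                            self.class_areas):
            rows.append({"threshold_percent": t, "stable_area_km2": a, **cl})
        return pd.DataFrame(rows)


def stable_area_sweep(guild_richness_by_scenario:
                      Dict[str, Dict[str, np.ndarray]],
                      guild_totals: Dict[str, int],
                      pa_mask: np.ndarray, deforest_mask: np.ndarray,
                      thresholds: Sequence[int] = DEFAULT_GUILD_THRESHOLDS,
                      min_coincidence: int = 6,
                      cell_area_km2: float = 100.0) -> StableAreaResult:
    """Full stable-area analysis across guild thresholds.

    ``guild_richness_by_scenario`` maps scenario -> guild -> richness
    map (all 7 scenarios). For each threshold X the per-scenario
    qualification masks are combined into a coincidence count, a
    stability mask, and a protected/deforested/intact partition. Stable
    area is monotonically non-increasing in X.
    """
    scenarios = list(guild_richness_by_scenario)
    result = StableAreaResult(thresholds=[], stable_area_km2=[],
                              class_areas=[])
    for x in thresholds:
        masks = [guild_threshold_mask(guild_richness_by_scenario[s],
                                      guild_totals, x)
                 for s in scenarios]
        _, stable = stability_map(masks, n_scenarios=len(scenarios),
                                  min_coincidence=min_coincidence)
        cls, areas = classify_stable_cells(stable, pa_mask, deforest_mask,
                                           cell_area_km2)
        result.thresholds.append(int(x))
        result.stable_area_km2.append(areas["stable_total_km2"])
        result.class_areas.append(areas)
        result.classification[int(x)] = cls
    return result
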