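"""Partitioning projection uncertainty across algorithms and scenarios.

For each grid cell, the richness values predicted under every
(algorithm, future scenario) combination form a two-way single-replicate
table. Main-effects sums of squares attribute the cell's variation to
the algorithm choice and the scenario choice; the interaction is
confounded with the residual in a single-replicate layout and is
reported as residual. Proportions are each SS over the total SS, so per
cell they sum to one; cells with zero total variation are masked as
undefined.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Sequence, Tuple

import numpy as np


@dataclass
class UncertaintyMaps:
    """Per-cell proportion-of-variation maps (NaN where undefined)."""
    algorithm: np.ndarray
    scenario: np.ndarray
    residual: np.ndarray
    mask: np.ndarray  # True where the decomposition is defined


def partition_uncertainty(richness: Dict[Tuple[str, str], np.ndarray]
                          ) -> UncertaintyMaps:
    """Two-way main-effects SS decomposition per cell.

    ``richness`` maps (algorithm, scenario_id) -> richness map; the
    factorial must be complete (every algorithm under every scenario).
    Current-scenario maps should not be included: uncertainty is
    partitioned across futures only.
    """
    algos = sorted({a for a, _ in richness})
    scens = sorted({s for _, s in richness})
    for a in algos:
        for s in scens:
            if (a, s) not in richness:
                raise ValueError(f"incomplete factorial: missing ({a}, {s})")
    shape = next(iter(richness.values())).shape
    # y: (n_algo, n_scen, rows, cols)
    y = np.stack([
        np.stack([np.asarray(richness[(a, s)], dtype=float) for s in scens])
        for a in algos
    ])
    na, ns = len(algos), len(scens)
    grand = y.mean(axis=(0, 1))
    mean_a = y.mean(axis=1)  # (na, r, c)
    mean_s = y.mean(axis=0)  # (ns, r, c)
    ss_a = ns * ((mean_a - grand) ** 2).sum(axis=0)
    ss_s = na * ((mean_s - grand) ** 2).sum(axis=0)
    ss_tot = ((y - grand) ** 2).sum(axis=(0, 1))
    ss_res = ss_tot - ss_a - ss_s
    defined = ss_tot > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        p_a = np.where(defined, ss_a / ss_tot, np.nan)
        p_s = np.where(defined, ss_s / ss_tot, np.nan)
        p_r = np.where(defined, ss_res / ss_tot, np.nan)
    # numerical floor: residual SS can come out at tiny negative values
    p_r = np.where(defined, np.clip(p_r, 0.0, 1.0), np.nan)
    return UncertaintyMaps(algorithm=p_a, scenario=p_s, residual=p_r,
                           mask=defined)


def summarize_uncertainty(maps: UncertaintyMaps,
                          region_mask: np.ndarray | None = None
                          ) -> Dict[str, Tuple[float, float, float]]:
    """(median, min, max) of each factor's proportion, in percent.

    Statistics are taken over cells where the decomposition is defined,
    optionally intersected with a region mask (e.g. a habitat group's
    occupied extent). Raises if no defined cell remains.
    """
    sel = maps.mask if region_mask is None else (maps.mask
                                                 & np.asarray(region_mask))
    if not np.any(sel):
        raise ValueError("no cell with a defined decomposition in region")
    out = {}
    for name, arr in (("algorithm", maps.algorithm),
                      ("scenario", maps.scenario),
                      ("residual", maps.residual)):
        v = 100.0 * arr[sel]
        out[name] = (float(np.median(v)), float(v.min()), float(v.max()))
    return out
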