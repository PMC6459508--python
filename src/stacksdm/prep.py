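"""Occurrence quality control and predictor selection.

Two filters dominate presence-record QC at this grain: spatial thinning
to a minimum inter-record distance (10 km by default, one grid cell),
which removes local sampling aggregation, and collinearity pruning of
the candidate climate layers at |Pearson r| > 0.85, which removes
redundant predictors before model fitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .grid import ClimateStack, GridSpec


@dataclass(frozen=True)
class ThinningConfig:
    min_distance_km: float = 10.0

    def __post_init__(self) -> None:
        if self.min_distance_km <= 0:
            raise ValueError("min_distance_km must be > 0")


@dataclass
class PredictorSelection:
    retained: List[str]
    dropped: List[Tuple[str, str, float]] = field(default_factory=list)
    # (dropped variable, retained partner it correlated with, r)


def thin_occurrences(points: np.ndarray, config: ThinningConfig,
                     seed: int = 0) -> np.ndarray:
    """Greedy randomized spatial thinning.

    Visits records in a seed-controlled random order and keeps a record
    iff its distance to every already-kept record is at least
    ``min_distance_km``. The output therefore satisfies the pairwise
    minimum-distance constraint exactly, checkable by brute force.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if pts.shape[0] == 0:
        raise ValueError("no records to thin")
    if pts.shape[0] == 1:
        return pts.copy()
    rng = np.random.default_rng(seed)
    order = rng.permutation(pts.shape[0])
    kept: List[int] = []
    d_min2 = config.min_distance_km ** 2
    for i in order:
        p = pts[i]
        ok = True
        for j in kept:
            d2 = (p[0] - pts[j, 0]) ** 2 + (p[1] - pts[j, 1]) ** 2
            if d2 < d_min2:
                ok = False
                break
        if ok:
            kept.append(i)
    return pts[np.sort(kept)]


def min_pairwise_distance(points: np.ndarray) -> float:
    """Exhaustive O(n^2) minimum pairwise distance (inf for < 2 points)."""
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if pts.shape[0] < 2:
        return float("inf")
    return float(pdist(pts).min())


def centroid_outlier_filter(points: np.ndarray,
                            quantile: float = 0.99) -> np.ndarray:
    """Optional automated stand-in for manual removal of disparate records.

    Drops records whose distance from the point centroid exceeds the
    given quantile of those distances. Off by default in the pipeline.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if pts.shape[0] < 3:
        return pts.copy()
    d = np.hypot(*(pts - pts.mean(axis=0)).T)
    return pts[d <= np.quantile(d, quantile)]


def select_predictors(stack: ClimateStack, threshold: float = 0.85,
                      priority: Optional[Sequence[str]] = None
                      ) -> PredictorSelection:
    """Iterative collinearity pruning of climate layers.

    While any retained pair has |Pearson r| above the threshold, the
    lower-priority member of the worst-offending pair is dropped
    (default priority = input layer order, earlier = higher priority).
    Zero-variance layers are dropped up front since r is undefined for
    them. The retained set is guaranteed to have max |r| <= threshold.
    """
    names = list(priority) if priority is not None else stack.layer_names
    if len(names) < 2:
        raise ValueError("need at least 2 layers to select predictors")
    dropped: List[Tuple[str, str, float]] = []

    flat = {n: stack[n].ravel() for n in names}
    retained = []
    for n in names:
        if flat[n].std() == 0:
            dropped.append((n, "", float("nan")))
        else:
            retained.append(n)

    def corr(a: str, b: str) -> float:
        return float(np.corrcoef(flat[a], flat[b])[0, 1])

    while True:
        worst: Tuple[float, int, int] | None = None
        for i in range(len(retained)):
            for j in range(i + 1, len(retained)):
                r = abs(corr(retained[i], retained[j]))
                if r > threshold and (worst is None or r > worst[0]):
                    worst = (r, i, j)
        if worst is None:
            break
        r, i, j = worst
        # drop the later (lower-priority) member of the pair
        dropped.append((retained[j], retained[i], r))
        del retained[j]
    return PredictorSelection(retained=retained, dropped=dropped)


def max_abs_correlation(stack: ClimateStack,
                        names: Sequence[str]) -> float:
    """Max |Pearson r| over all pairs of the named layers."""
    mat = np.corrcoef(np.stack([stack[n].ravel() for n in names]))
    off = np.abs(mat - np.eye(len(names)))
    return float(off.max())


def build_samples(points: np.ndarray, stack: ClimateStack,
                  layer_names: Optional[Sequence[str]] = None) -> np.ndarray:
    """Extract predictor vectors at each record's containing cell.

    Cell membership uses the grid's half-open [edge, edge + cell_size)
    convention. Records outside the grid extent raise ``ValueError``
    naming the offending record.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    names = list(layer_names) if layer_names is not None else stack.layer_names
    out = np.empty((pts.shape[0], len(names)))
    for i, (x, y) in enumerate(pts):
        try:
            row, col = stack.grid.cell_of(x, y)
        except ValueError as exc:
            raise ValueError(f"record {i} at ({x}, {y}) is out of bounds: "
                             f"{exc}") from None
        for k, n in enumerate(names):
            out[i, k] = stack[n][row, col]
    return out


def presence_cells(points: np.ndarray, grid: GridSpec) -> np.ndarray:
    """Boolean grid marking cells containing at least one record."""
    mask = np.zeros(grid.shape, dtype=bool)
    for x, y in np.asarray(points, dtype=float).reshape(-1, 2):
        row, col = grid.cell_of(x, y)
        mask[row, col] = True
    return mask


def exclude_small_ranges(binary_maps: dict[str, np.ndarray],
                         min_cells: int = 100) -> List[str]:
    """Retain species whose current binary range covers >= min_cells cells.

    Species with fewer presence cells are excluded to avoid
    overinterpreting marginal projections.
    """
    return [sp for sp, m in binary_maps.items()
            if int(np.asarray(m).sum()) >= min_cells]
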