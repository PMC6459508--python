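"""Repeated-split model evaluation: TSS, ROC AUC and cutoff selection.

Skill is assessed on stratified 80/20 calibration/evaluation splits,
repeated ten times. The True Skill Statistic (TSS = sensitivity +
specificity - 1) is maximized exactly over all distinct observed scores
as candidate cutoffs; ROC AUC is the normalized Mann-Whitney U (ties
count one half). Replicates with TSS below 0.5 are eliminated before
ensemble building.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np


@dataclass
class EvaluationRecord:
    """Held-out skill of one model replicate."""
    algorithm: str
    pa_set_id: int
    repeat_id: int
    tss: float
    roc_auc: float
    sensitivity: float
    specificity: float
    cutoff: float

    @property
    def key(self) -> Tuple[str, int, int]:
        return (self.algorithm, self.pa_set_id, self.repeat_id)


class NoSkilledModelError(RuntimeError):
    """All replicates of a species fell below the skill floor."""


def split_data(labels: np.ndarray, calib_fraction: float = 0.8,
               n_repeats: int = 10, seed: int = 0,
               max_retries: int = 100
               ) -> List[Tuple[np.ndarray, np.ndarray]]:
    """Stratified repeated calibration/evaluation splits.

    Each repeat partitions the indices into a calibration set holding
    ``calib_fraction`` of each class and an evaluation set with the
    rest; both partitions are guaranteed to contain both classes
    (bounded resampling, then error).
    """
    y = np.asarray(labels)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("labels must contain both classes")
    rng = np.random.default_rng(seed)
    splits = []
    for _ in range(n_repeats):
        for _attempt in range(max_retries):
            calib_idx = []
            for c in classes:
                idx = np.flatnonzero(y == c)
                k = int(round(calib_fraction * idx.size))
                calib_idx.append(rng.choice(idx, size=k, replace=False))
            calib = np.sort(np.concatenate(calib_idx))
            evalu = np.setdiff1d(np.arange(y.size), calib)
            if (np.unique(y[calib]).size == classes.size
                    and np.unique(y[evalu]).size == classes.size):
                splits.append((calib, evalu))
                break
        else:
            raise ValueError("could not build a split with both classes "
                             "in both partitions")
    return splits


def tss_curve(scores: Sequence[float], labels: Sequence[int]
              ) -> Tuple[float, float, float, float]:
    """Exact TSS maximization over observed score cutoffs.

    A prediction is positive iff score >= cutoff; every distinct score is
    tried as a cutoff. Returns (best_tss, best_cutoff, sensitivity,
    specificity) at the optimum, ties broken by the lowest cutoff.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("labels must contain both classes")
    cutoffs = np.unique(s)  # ascending
    best = None
    for c in cutoffs:
        pred = s >= c
        sens = float((pred & (y == 1)).sum()) / n_pos
        spec = float((~pred & (y == 0)).sum()) / n_neg
        tss = sens + spec - 1.0
        if best is None or tss > best[0] + 1e-12:
            best = (tss, float(c), sens, spec)
    return best


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """ROC AUC as the normalized Mann-Whitney U statistic.

    Equals the probability that a random positive outscores a random
    negative, with ties counted one half.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    pos = s[y == 1]
    neg = s[y == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("labels must contain both classes")
    # rank-based U avoids the O(n1*n0) pair loop
    order = np.argsort(np.concatenate([pos, neg]), kind="mergesort")
    ranks = np.empty(order.size, dtype=float)
    ranks[order] = np.arange(1, order.size + 1)
    # midranks for ties
    allv = np.concatenate([pos, neg])
    sorted_v = allv[order]
    i = 0
    while i < sorted_v.size:
        j = i
        while j + 1 < sorted_v.size and sorted_v[j + 1] == sorted_v[i]:
            j += 1
        if j > i:
            ranks[order[i:j + 1]] = (i + 1 + j + 1) / 2.0
        i = j + 1
    u = ranks[:pos.size].sum() - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


def filter_models(records: Sequence[EvaluationRecord],
                  tss_min: float = 0.5) -> List[Tuple[str, int, int]]:
    """Keys of replicates admitted to the ensemble (TSS >= tss_min).

    The boundary is inclusive: a replicate at exactly the floor is kept.
    Raises ``NoSkilledModelError`` if nothing survives.
    """
    kept = [r.key for r in records if r.tss >= tss_min]
    if not kept:
        raise NoSkilledModelError(
            f"no replicate reached TSS >= {tss_min}")
    return kept


def evaluate_replicate(algorithm: str, pa_set_id: int, repeat_id: int,
                       scores: np.ndarray, labels: np.ndarray
                       ) -> EvaluationRecord:
    """Bundle held-out TSS/ROC/sens/spec/cutoff for one replicate."""
    tss, cutoff, sens, spec = tss_curve(scores, labels)
    return EvaluationRecord(
        algorithm=algorithm, pa_set_id=pa_set_id, repeat_id=repeat_id,
        tss=tss, roc_auc=roc_auc(scores, labels),
        sensitivity=sens, specificity=spec, cutoff=cutoff)
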