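"""Committee-average consensus and multi-scenario projection.

Each retained model replicate is binarized at its own TSS-maximizing
cutoff; the consensus is the per-cell mean of those binary votes, so
consensus values are exact multiples of 1/m for m members. The consensus
map is itself binarized at a single ensemble-level cutoff estimated on
current-scenario evaluation data and reused for every future scenario
(futures have no evaluation data, so no per-scenario cutoff exists).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .grid import ClimateStack
from .models import FittedModel, predict_suitability
from .evaluation import tss_curve


@dataclass
class ScenarioMapSet:
    """Per-species consensus and binary maps across all scenarios."""
    species_id: str
    maps: Dict[str, np.ndarray] = field(default_factory=dict)
    binary: Dict[str, np.ndarray] = field(default_factory=dict)
    cutoff: float = 0.5

    @property
    def scenario_ids(self) -> List[str]:
        return list(self.maps)


def committee_average(member_maps: Sequence[np.ndarray],
                      member_cutoffs: Sequence[float]) -> np.ndarray:
    """Mean of member binary votes at each cell.

    Each member's suitability map is thresholded at that member's own
    cutoff (vote = 1 iff score >= cutoff) and the votes are averaged.
    """
    if len(member_maps) == 0:
        raise ValueError("need at least one retained member")
    if len(member_maps) != len(member_cutoffs):
        raise ValueError("one cutoff per member required")
    shape = np.asarray(member_maps[0]).shape
    votes = np.zeros(shape, dtype=float)
    for m, c in zip(member_maps, member_cutoffs):
        m = np.asarray(m)
        if m.shape != shape:
            raise ValueError("member maps are not on a common grid")
        votes += (m >= c)
    return votes / len(member_maps)


def binarize_consensus(consensus: np.ndarray, sample_scores: np.ndarray,
                       sample_labels: np.ndarray
                       ) -> Tuple[np.ndarray, float]:
    """Threshold a consensus map at its TSS-maximizing cutoff.

    The cutoff is estimated from consensus scores at evaluation sample
    locations versus their presence/absence labels; the binary map is
    consensus >= cutoff.
    """
    _, cutoff, _, _ = tss_curve(sample_scores, sample_labels)
    return (consensus >= cutoff).astype(np.uint8), cutoff


def project_all_scenarios(species_id: str,
                          members: Sequence[FittedModel],
                          member_cutoffs: Sequence[float],
                          stacks: Dict[str, ClimateStack],
                          eval_scores: np.ndarray,
                          eval_labels: np.ndarray) -> ScenarioMapSet:
    """Project every retained member onto every scenario stack.

    Produces one consensus map per scenario via committee averaging and
    binarizes all of them at the single ensemble cutoff fitted on the
    current-scenario evaluation samples (``eval_scores`` are consensus
    values at those sample locations).
    """
    if "current" not in stacks:
        raise ValueError("scenario set must include 'current'")
    out = ScenarioMapSet(species_id=species_id)
    _, cutoff, _, _ = tss_curve(eval_scores, eval_labels)
    out.cutoff = cutoff
    for sid, stack in stacks.items():
        preds = [predict_suitability(m, stack) for m in members]
        cons = committee_average(preds, member_cutoffs)
        out.maps[sid] = cons
        out.binary[sid] = (cons >= cutoff).astype(np.uint8)
    return out
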