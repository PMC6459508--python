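"""Virtual-species testbed: climate surfaces, species truths, sampling, masks.

Every downstream stage of the pipeline (QC, model fitting, ensembles,
richness stacking, uncertainty and conservation overlays) is exercised
against worlds built here, where the true occurrence probability of each
species is known exactly. The generators are pure functions of their
arguments and a seed.

The truth model is a Gaussian-bump logistic niche: per cell,

    p = logistic(a + sum_v w_v * exp(-(x_v - opt_v)^2 / (2 * breadth_v^2)))

with the intercept ``a`` calibrated by root finding so that the grid-mean
probability matches a prevalence target. Smooth, unimodal responses of
this form are recoverable by both model families fitted downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage, optimize
from scipy.special import expit

from .grid import ClimateStack, GridSpec

GUILDS = ("FR", "IN", "NE", "OT")
HABITATS = ("FT", "OAV")

#: scenario ids for the default experiment: present climate plus three
#: emissions pathways at two horizons (7 scenarios in total).
DEFAULT_SCENARIOS = (
    "current",
    "rcp26_2050", "rcp26_2070",
    "rcp60_2050", "rcp60_2070",
    "rcp85_2050", "rcp85_2070",
)

#: additive warming applied to the first climate axis under each future
#: scenario, in within-grid standard deviations. Magnitudes rise with the
#: pathway's severity and the time horizon.
DEFAULT_WARMING_SD = {
    "rcp26_2050": 0.8, "rcp26_2070": 1.0,
    "rcp60_2050": 1.2, "rcp60_2070": 1.6,
    "rcp85_2050": 1.6, "rcp85_2070": 2.2,
}


@dataclass(frozen=True)
class ResponseParam:
    """One variable's contribution to a species' niche."""
    optimum: float
    breadth: float
    weight: float

    def __post_init__(self) -> None:
        if self.breadth <= 0:
            raise ValueError("breadth must be > 0")
        if not np.isfinite(self.weight):
            raise ValueError("weight must be finite")


@dataclass(frozen=True)
class VirtualSpeciesTruth:
    """Ground-truth description of one simulated species."""
    species_id: str
    guild: str
    habitat: str
    response_params: Dict[str, ResponseParam]
    prevalence_target: float = 0.2

    def __post_init__(self) -> None:
        if self.guild not in GUILDS:
            raise ValueError(f"guild must be one of {GUILDS}")
        if self.habitat not in HABITATS:
            raise ValueError(f"habitat must be one of {HABITATS}")
        if not (0 < self.prevalence_target < 1):
            raise ValueError("prevalence_target must be in (0, 1)")


@dataclass
class OccurrenceSet:
    """Presence records plus per-species guild/habitat metadata."""
    records: List[Tuple[str, float, float]]
    species_meta: Dict[str, Tuple[str, str]] = field(default_factory=dict)

    def for_species(self, species_id: str) -> np.ndarray:
        """(n, 2) array of x_km, y_km for one species."""
        pts = [(x, y) for s, x, y in self.records if s == species_id]
        return np.array(pts, dtype=float).reshape(-1, 2)

    @property
    def species_ids(self) -> List[str]:
        seen: Dict[str, None] = {}
        for s, _, _ in self.records:
            seen.setdefault(s)
        return list(seen)


def generate_climate_stack(grid: GridSpec, n_vars: int,
                           autocorr_scale: float = 80.0,
                           seed: int = 0,
                           scenario_id: str = "current") -> ClimateStack:
    """Spatially autocorrelated, standardized climate surfaces.

    Each layer is Gaussian-filtered white noise (filter sigma =
    ``autocorr_scale`` km converted to cells), standardized to zero mean
    and unit variance over the grid. Deterministic under a fixed seed.
    """
    if n_vars < 1:
        raise ValueError("n_vars must be >= 1")
    if autocorr_scale <= 0:
        raise ValueError("autocorr_scale must be > 0")
    rng = np.random.default_rng(seed)
    sigma_cells = autocorr_scale / grid.cell_size_km
    layers: Dict[str, np.ndarray] = {}
    for i in range(n_vars):
        raw = rng.standard_normal(grid.shape)
        smooth = ndimage.gaussian_filter(raw, sigma=sigma_cells,
                                         mode="reflect")
        smooth = (smooth - smooth.mean()) / smooth.std()
        layers[f"bio{i + 1}"] = smooth
    return ClimateStack(grid=grid, scenario_id=scenario_id, layers=layers)


def apply_scenario_shift(stack: ClimateStack,
                         shifts: Dict[str, float | Tuple[float, str]],
                         scenario_id: str) -> ClimateStack:
    """Additive per-layer climate deltas, optionally ramped spatially.

    ``shifts`` maps layer name -> delta, or -> (delta, direction) where
    direction in {"ns", "ew"} ramps the delta linearly from 0 to
    2*delta along the given axis (mean shift stays equal to delta).
    Unshifted layers are copied unchanged.
    """
    out = stack.copy(scenario_id=scenario_id)
    for name, spec in shifts.items():
        if name not in out:
            raise KeyError(f"unknown layer {name!r} in scenario shift")
        if isinstance(spec, tuple):
            delta, direction = spec
            nr, nc = out.grid.shape
            if direction == "ns":
                ramp = np.linspace(0.0, 2.0 * delta, nr)[:, None]
                field_ = np.broadcast_to(ramp, (nr, nc))
            elif direction == "ew":
                ramp = np.linspace(0.0, 2.0 * delta, nc)[None, :]
                field_ = np.broadcast_to(ramp, (nr, nc))
            else:
                raise ValueError(f"unknown gradient direction {direction!r}")
            out.layers[name] = out.layers[name] + field_
        else:
            out.layers[name] = out.layers[name] + float(spec)
    return out


def _niche_score(stack: ClimateStack, truth: VirtualSpeciesTruth) -> np.ndarray:
    """Sum of weighted Gaussian responses, before intercept/logistic."""
    score = np.zeros(stack.grid.shape)
    for var, rp in truth.response_params.items():
        if var not in stack:
            raise KeyError(f"response references unknown layer {var!r}")
        x = stack[var]
        score += rp.weight * np.exp(-0.5 * ((x - rp.optimum) / rp.breadth) ** 2)
    return score


class PrevalenceCalibrationError(RuntimeError):
    """Raised when no intercept can reach the prevalence target."""


def generate_virtual_species(stack: ClimateStack,
                             truth: VirtualSpeciesTruth,
                             tol: float = 1e-4) -> np.ndarray:
    """True per-cell occurrence probability for one species.

    The intercept is calibrated by bisection so the grid-mean probability
    hits ``truth.prevalence_target`` to within ``tol`` (well inside the
    0.01 contract).
    """
    score = _niche_score(stack, truth)
    target = truth.prevalence_target

    def mean_prev(a: float) -> float:
        return float(expit(a + score).mean())

    lo, hi = -50.0, 50.0
    if not (mean_prev(lo) - target < 0 < mean_prev(hi) - target):
        raise PrevalenceCalibrationError(
            f"prevalence target {target} unreachable for {truth.species_id}")
    a = optimize.brentq(lambda v: mean_prev(v) - target, lo, hi, xtol=1e-8)
    p = expit(a + score)
    assert abs(p.mean() - target) <= max(tol, 1e-3)
    return p


def sample_occurrences(true_prob_map: np.ndarray, grid: GridSpec,
                       n_presences: int, seed: int,
                       bias_map: Optional[np.ndarray] = None,
                       species_id: str = "sp",
                       guild: str = "OT",
                       habitat: str = "FT") -> OccurrenceSet:
    """Presence-only sampling proportional to truth x observer bias.

    Cells are drawn with replacement with probability proportional to
    p(cell) * bias(cell); each draw is jittered uniformly within its
    cell, and exact coordinate duplicates are removed (they cannot occur
    with continuous jitter, but the contract is enforced regardless).
    """
    if n_presences < 1:
        raise ValueError("n_presences must be >= 1")
    rng = np.random.default_rng(seed)
    w = np.asarray(true_prob_map, dtype=float).ravel().copy()
    if bias_map is not None:
        w = w * np.asarray(bias_map, dtype=float).ravel()
    if w.sum() <= 0:
        raise ValueError("all-zero sampling weights")
    w = w / w.sum()
    cells = rng.choice(w.size, size=n_presences, replace=True, p=w)
    rows, cols = np.unravel_index(cells, grid.shape)
    x0, y0 = grid.origin
    xs = x0 + (cols + rng.uniform(0, 1, n_presences)) * grid.cell_size_km
    ys = y0 + (rows + rng.uniform(0, 1, n_presences)) * grid.cell_size_km
    seen = set()
    records = []
    for x, y in zip(xs, ys):
        key = (float(x), float(y))
        if key in seen:
            continue
        seen.add(key)
        records.append((species_id, float(x), float(y)))
    return OccurrenceSet(records=records,
                         species_meta={species_id: (guild, habitat)})


def clustered_bias_map(grid: GridSpec, n_hotspots: int = 5,
                       hotspot_scale_km: float = 60.0,
                       base: float = 0.1, seed: int = 0) -> np.ndarray:
    """Observer-effort surface emulating roadside/settlement sampling bias.

    A constant floor plus Gaussian hotspots of effort; values in (0, 1].
    """
    rng = np.random.default_rng(seed)
    nr, nc = grid.shape
    yy, xx = np.mgrid[0:nr, 0:nc]
    sigma = hotspot_scale_km / grid.cell_size_km
    bias = np.full(grid.shape, base)
    for _ in range(n_hotspots):
        cy, cx = rng.uniform(0, nr), rng.uniform(0, nc)
        bias += np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma ** 2))
    return bias / bias.max()


def generate_masks(grid: GridSpec, n_pa_blocks: int,
                   deforest_fraction: float, seed: int,
                   min_block_cells: int = 10
                   ) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Protected-area blocks and a clumped deforestation mask.

    Returns ``(pa_mask, pa_block_ids, deforest_mask)``. PA blocks are
    disjoint axis-aligned rectangles of at least ``min_block_cells``
    cells each (>= 1,000 km^2 at the 10 km default), labelled 1..n in
    ``pa_block_ids`` (0 = unprotected). Deforestation is spatially
    clumped (thresholded smoothed noise) and covers ``deforest_fraction``
    of non-PA cells to within 0.02.
    """
    if not (0.0 <= deforest_fraction <= 1.0):
        raise ValueError("deforest_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    nr, nc = grid.shape
    pa_ids = np.zeros(grid.shape, dtype=int)

    placed = 0
    attempts = 0
    max_attempts = 2000
    while placed < n_pa_blocks:
        attempts += 1
        if attempts > max_attempts:
            raise ValueError(
                f"could not fit {n_pa_blocks} disjoint PA blocks of "
                f">= {min_block_cells} cells on a {nr}x{nc} grid")
        h = rng.integers(3, max(4, nr // 4) + 1)
        w = rng.integers(3, max(4, nc // 4) + 1)
        if h * w < min_block_cells or h > nr or w > nc:
            continue
        r0 = rng.integers(0, nr - h + 1)
        c0 = rng.integers(0, nc - w + 1)
        if np.any(pa_ids[r0:r0 + h, c0:c0 + w] != 0):
            continue
        placed += 1
        pa_ids[r0:r0 + h, c0:c0 + w] = placed
    pa_mask = pa_ids > 0

    deforest = np.zeros(grid.shape, dtype=bool)
    if deforest_fraction > 0:
        noise = ndimage.gaussian_filter(rng.standard_normal(grid.shape),
                                        sigma=2.0, mode="reflect")
        outside = ~pa_mask
        n_out = int(outside.sum())
        k = int(round(deforest_fraction * n_out))
        if k > 0:
            vals = noise[outside]
            # threshold at the k-th largest value among non-PA cells so the
            # achieved fraction is exact up to ties
            thresh = np.partition(vals, n_out - k)[n_out - k]
            deforest = outside & (noise >= thresh)
    return pa_mask, pa_ids, deforest


def generate_community(stack: ClimateStack, n_species: int, seed: int,
                       prevalence: float = 0.2,
                       breadth_range: Tuple[float, float] = (0.8, 1.2),
                       weight_range: Tuple[float, float] = (10.0, 16.0),
                       n_response_vars: int = 2,
                       oav_fraction: float = 0.3
                       ) -> List[VirtualSpeciesTruth]:
    """A guild-structured community of virtual species.

    Habitat classes encode thermal strategy on the first climate axis:
    forest (FT) species are cool-adapted (optimum drawn from the lower
    part of the current range of layer bio1), open-area (OAV) species are
    warm-adapted (upper part). Under the default warming scenarios this
    yields the qualitative contrast the pipeline must resolve: FT ranges
    contract, OAV ranges hold or expand. Guilds are assigned round-robin
    so that every guild is represented whenever n_species >= 4.
    """
    rng = np.random.default_rng(seed)
    names = stack.layer_names
    if n_response_vars > len(names):
        raise ValueError("n_response_vars exceeds available layers")
    truths: List[VirtualSpeciesTruth] = []
    v1 = stack[names[0]]
    lo, hi = float(v1.min()), float(v1.max())
    span = hi - lo
    for i in range(n_species):
        habitat = "OAV" if rng.uniform() < oav_fraction else "FT"
        guild = GUILDS[i % len(GUILDS)]
        if habitat == "FT":
            opt1 = lo + span * rng.uniform(0.05, 0.35)
        else:
            opt1 = lo + span * rng.uniform(0.70, 0.95)
        params = {names[0]: ResponseParam(
            optimum=opt1,
            breadth=float(rng.uniform(*breadth_range)),
            weight=float(rng.uniform(*weight_range)))}
        extra = rng.choice(len(names) - 1, size=n_response_vars - 1,
                           replace=False) + 1
        for j in extra:
            layer = stack[names[j]]
            params[names[j]] = ResponseParam(
                optimum=float(rng.uniform(layer.min(), layer.max())),
                breadth=float(rng.uniform(*breadth_range)),
                weight=float(rng.uniform(1.0, 3.0)))
        truths.append(VirtualSpeciesTruth(
            species_id=f"sp{i + 1:03d}", guild=guild, habitat=habitat,
            response_params=params, prevalence_target=prevalence))
    return truths


def default_scenario_stacks(stack: ClimateStack,
                            warming_sd: Dict[str, float] | None = None
                            ) -> Dict[str, ClimateStack]:
    """Current plus six future stacks with increasing warming on bio1."""
    warming_sd = warming_sd if warming_sd is not None else DEFAULT_WARMING_SD
    first = stack.layer_names[0]
    stacks = {"current": stack.copy(scenario_id="current")}
    for sid, delta in warming_sd.items():
        stacks[sid] = apply_scenario_shift(stack, {first: delta}, sid)
    return stacks
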