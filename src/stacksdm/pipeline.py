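"""End-to-end pipeline: synthetic world -> QC -> models -> ensembles ->
richness, uncertainty and conservation products.

The driver follows the standard stacked-SDM protocol: per species, three
pseudo-absence sets with ten times the presences; ten stratified 80/20
calibration/evaluation splits per set; GLM and maxent-like fits per
split; replicates below TSS 0.5 eliminated; committee-average consensus
projected to all seven climate scenarios and binarized at the species'
TSS-maximizing cutoff; species with fewer than 100 current presence
cells excluded; then richness stacking, two-way uncertainty
partitioning, PA effectiveness and the stable-area sweep.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from . import assemblage, conservation, ensemble, evaluation, models, prep
from .grid import ClimateStack, GridSpec
from .synthetic import (DEFAULT_WARMING_SD, GUILDS, OccurrenceSet,
                        VirtualSpeciesTruth, clustered_bias_map,
                        default_scenario_stacks, generate_climate_stack,
                        generate_community, generate_masks,
                        generate_virtual_species, sample_occurrences)

logger = logging.getLogger("stacksdm")


@dataclass
class PipelineConfig:
    """All knobs of a synthetic-mode run, with protocol defaults."""
    n_rows: int = 60
    n_cols: int = 60
    cell_size_km: float = 10.0
    n_climate_vars: int = 5
    autocorr_scale_km: float = 80.0
    n_species: int = 20
    prevalence: float = 0.2
    #: presence draws per species; after 10 km thinning this leaves room
    #: for ten times as many background cells on the default 60x60 grid
    n_presences: int = 400
    oav_fraction: float = 0.3
    warming_sd: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_WARMING_SD))
    # QC / selection
    min_dist_km: float = 10.0
    cor_threshold: float = 0.85
    min_cells: int = 100
    # modelling protocol
    pa_multiplier: int = 10
    n_pa_sets: int = 3
    calib_fraction: float = 0.8
    n_repeats: int = 10
    tss_min: float = 0.5
    # conservation
    n_pa_blocks: int = 13
    deforest_fraction: float = 0.15
    guild_thresholds: Tuple[int, ...] = conservation.DEFAULT_GUILD_THRESHOLDS
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.calib_fraction < 1):
            raise ValueError("calib_fraction must be in (0, 1)")
        if not (0 <= self.tss_min <= 1):
            raise ValueError("tss_min must be in [0, 1]")

    @property
    def scenario_ids(self) -> List[str]:
        return ["current"] + list(self.warming_sd)


@dataclass
class SpeciesResult:
    """Everything the pipeline keeps for one retained species."""
    truth: VirtualSpeciesTruth
    true_prob: np.ndarray
    map_set: ensemble.ScenarioMapSet
    algo_binary: Dict[str, Dict[str, np.ndarray]]  # algorithm -> scen -> map
    eval_records: List[evaluation.EvaluationRecord]
    retained_keys: List[Tuple[str, int, int]]
    mean_tss: float
    mean_roc: float


@dataclass
class PipelineResult:
    config: PipelineConfig
    stacks: Dict[str, ClimateStack]
    selection: prep.PredictorSelection
    occurrences: OccurrenceSet
    species: Dict[str, SpeciesResult]
    excluded: Dict[str, str]  # species -> reason
    range_table: pd.DataFrame
    census: pd.DataFrame
    guild_summary: pd.DataFrame
    richness: Dict[str, assemblage.RichnessMap]
    uncertainty_maps: object
    uncertainty_summary: Dict[str, Tuple[float, float, float]]
    pa_report: pd.DataFrame
    stable: conservation.StableAreaResult
    pa_mask: np.ndarray
    pa_block_ids: np.ndarray
    deforest_mask: np.ndarray

    def summary(self) -> dict:
        sp = self.species
        return {
            "n_species_modelled": len(sp) + len(self.excluded),
            "n_species_retained": len(sp),
            "n_scenarios": len(self.stacks),
            "retained_predictors": self.selection.retained,
            "mean_tss": round(float(np.mean(
                [s.mean_tss for s in sp.values()])), 6) if sp else None,
            "mean_roc": round(float(np.mean(
                [s.mean_roc for s in sp.values()])), 6) if sp else None,
            "stable_area_km2": dict(zip(
                map(str, self.stable.thresholds),
                self.stable.stable_area_km2)),
            "mean_pa_percent_lost": round(float(
                self.pa_report["percent_lost"].mean()), 6),
        }

    def summary_digest(self) -> str:
        blob = json.dumps(self.summary(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def _stage_seeds(seed: int, n: int) -> List[int]:
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2 ** 31 - 1, size=n)]


def fit_species(presence_pts: np.ndarray, stacks: Dict[str, ClimateStack],
                layer_names: List[str], config: PipelineConfig,
                seed: int, species_id: str = "sp"
                ) -> Tuple[Optional[ensemble.ScenarioMapSet],
                           Dict[str, Dict[str, np.ndarray]],
                           List[evaluation.EvaluationRecord],
                           List[Tuple[str, int, int]]]:
    """Model one species end to end: fits, evaluation, ensemble maps.

    Returns (map_set, per-algorithm binary maps, evaluation records,
    retained keys); map_set is None when no replicate clears the TSS
    floor.
    """
    current = stacks["current"]
    grid = current.grid
    seeds = _stage_seeds(seed, 4)
    pres_vec = prep.build_samples(presence_pts, current, layer_names)

    pa_sets = models.sample_pseudo_absences(
        presence_pts, grid, multiplier=config.pa_multiplier,
        n_sets=config.n_pa_sets, seed=seeds[0])

    eval_records: List[evaluation.EvaluationRecord] = []
    fitted: Dict[Tuple[str, int, int], models.FittedModel] = {}
    heldout: Dict[int, List[Tuple[np.ndarray, np.ndarray]]] = {}

    for pa in pa_sets:
        abs_vec = prep.build_samples(pa.points, current, layer_names)
        x = np.vstack([pres_vec, abs_vec])
        y = np.concatenate([np.ones(len(pres_vec)),
                            np.zeros(len(abs_vec))])
        splits = evaluation.split_data(
            y, calib_fraction=config.calib_fraction,
            n_repeats=config.n_repeats, seed=seeds[1] + pa.set_id)
        heldout[pa.set_id] = []
        for rep, (calib, evalu) in enumerate(splits, start=1):
            xp, xa = x[calib][y[calib] == 1], x[calib][y[calib] == 0]
            for algo in models.ALGORITHMS:
                if algo == "glm":
                    m = models.fit_glm(xp, xa, layer_names,
                                       pa_set_id=pa.set_id, repeat_id=rep)
                else:
                    m = models.fit_maxent_like(
                        xp, xa, layer_names, pa_set_id=pa.set_id,
                        repeat_id=rep, seed=seeds[2] + 100 * pa.set_id + rep)
                if not m.converged:
                    logger.warning("%s %s pa%d rep%d did not converge; "
                                   "excluded", species_id, algo,
                                   pa.set_id, rep)
                    continue
                scores = models.predict_vectors(m, x[evalu])
                rec = evaluation.evaluate_replicate(
                    algo, pa.set_id, rep, scores, y[evalu])
                fitted[rec.key] = m
                eval_records.append(rec)
            heldout[pa.set_id].append((x[evalu], y[evalu]))

    try:
        retained = evaluation.filter_models(eval_records,
                                            tss_min=config.tss_min)
    except evaluation.NoSkilledModelError:
        return None, {}, eval_records, []

    cutoffs = {r.key: r.cutoff for r in eval_records}
    members = [fitted[k] for k in retained]
    member_cutoffs = [cutoffs[k] for k in retained]

    # pooled held-out samples (each evaluation partition once per repeat)
    pooled_x = np.vstack([xs for sets in heldout.values()
                          for xs, _ in sets])
    pooled_y = np.concatenate([ys for sets in heldout.values()
                               for _, ys in sets])

    def consensus_scores(mbrs, cuts):
        votes = np.zeros(len(pooled_x))
        for m, c in zip(mbrs, cuts):
            votes += (models.predict_vectors(m, pooled_x) >= c)
        return votes / len(mbrs)

    map_set = ensemble.project_all_scenarios(
        species_id, members, member_cutoffs, stacks,
        consensus_scores(members, member_cutoffs), pooled_y)

    # per-algorithm committee maps (for uncertainty partitioning)
    algo_binary: Dict[str, Dict[str, np.ndarray]] = {}
    for algo in models.ALGORITHMS:
        keys = [k for k in retained if k[0] == algo]
        if not keys:
            continue
        mbrs = [fitted[k] for k in keys]
        cuts = [cutoffs[k] for k in keys]
        sc = consensus_scores(mbrs, cuts)
        _, cut, _, _ = evaluation.tss_curve(sc, pooled_y)
        algo_binary[algo] = {}
        for sid, stack in stacks.items():
            cons = ensemble.committee_average(
                [models.predict_suitability(m, stack) for m in mbrs], cuts)
            algo_binary[algo][sid] = (cons >= cut).astype(np.uint8)
    return map_set, algo_binary, eval_records, retained


def run_pipeline(config: PipelineConfig,
                 out_dir: Optional[str | Path] = None,
                 write_rasters: bool = False) -> PipelineResult:
    """Execute the full synthetic-mode analysis."""
    seeds = _stage_seeds(config.seed, 8)
    grid = GridSpec(config.n_rows, config.n_cols, config.cell_size_km)

    # --- synthetic world -------------------------------------------------
    base = generate_climate_stack(grid, config.n_climate_vars,
                                  config.autocorr_scale_km, seed=seeds[0])
    stacks = default_scenario_stacks(base, config.warming_sd)
    truths = generate_community(base, config.n_species, seed=seeds[1],
                                prevalence=config.prevalence,
                                oav_fraction=config.oav_fraction)
    bias = clustered_bias_map(grid, seed=seeds[2])
    pa_mask, pa_ids, deforest = generate_masks(
        grid, config.n_pa_blocks, config.deforest_fraction, seed=seeds[3])

    # --- predictor selection on the current stack ------------------------
    selection = prep.select_predictors(base, threshold=config.cor_threshold)
    layer_names = selection.retained

    all_records: List[Tuple[str, float, float]] = []
    meta: Dict[str, Tuple[str, str]] = {}
    species_results: Dict[str, SpeciesResult] = {}
    excluded: Dict[str, str] = {}
    sp_seeds = _stage_seeds(seeds[4], config.n_species)

    for truth, sp_seed in zip(truths, sp_seeds):
        true_p = generate_virtual_species(base, truth)
        occ = sample_occurrences(true_p, grid, config.n_presences,
                                 seed=sp_seed, bias_map=bias,
                                 species_id=truth.species_id,
                                 guild=truth.guild, habitat=truth.habitat)
        pts = occ.for_species(truth.species_id)
        thinned = prep.thin_occurrences(
            pts, prep.ThinningConfig(config.min_dist_km), seed=sp_seed + 1)
        all_records += [(truth.species_id, x, y) for x, y in thinned]
        meta[truth.species_id] = (truth.guild, truth.habitat)

        try:
            map_set, algo_binary, eval_records, retained = fit_species(
                thinned, stacks, layer_names, config, seed=sp_seed + 2,
                species_id=truth.species_id)
        except ValueError as exc:
            excluded[truth.species_id] = f"modelling failed: {exc}"
            logger.warning("species %s excluded: %s", truth.species_id, exc)
            continue
        if map_set is None:
            excluded[truth.species_id] = "no replicate with TSS >= 0.5"
            continue
        if int(map_set.binary["current"].sum()) < config.min_cells:
            excluded[truth.species_id] = (
                f"current range < {config.min_cells} cells")
            continue
        kept = [r for r in eval_records if r.key in set(retained)]
        species_results[truth.species_id] = SpeciesResult(
            truth=truth, true_prob=true_p, map_set=map_set,
            algo_binary=algo_binary, eval_records=eval_records,
            retained_keys=retained,
            mean_tss=float(np.mean([r.tss for r in kept])),
            mean_roc=float(np.mean([r.roc_auc for r in kept])))

    if not species_results:
        raise RuntimeError("pipeline retained no species")
    occurrences = OccurrenceSet(records=all_records, species_meta=meta)

    # --- assemblage ------------------------------------------------------
    map_sets = [s.map_set for s in species_results.values()]
    range_table = assemblage.build_range_change_table(
        map_sets, meta, cell_area_km2=grid.cell_area_km2)
    census = assemblage.loss_gain_census(range_table)
    guild_summary = assemblage.guild_area_summary(range_table)
    richness = {
        sid: assemblage.stack_richness(
            [s.map_set.binary[sid] for s in species_results.values()], sid)
        for sid in stacks
    }

    # --- uncertainty: per-algorithm richness under future scenarios ------
    future_ids = [s for s in stacks if s != "current"]
    from .uncertainty import partition_uncertainty, summarize_uncertainty
    rich_fact: Dict[Tuple[str, str], np.ndarray] = {}
    for algo in models.ALGORITHMS:
        with_algo = [s for s in species_results.values()
                     if algo in s.algo_binary]
        for sid in future_ids:
            rich_fact[(algo, sid)] = assemblage.stack_richness(
                [s.algo_binary[algo][sid] for s in with_algo], sid).counts
    unc_maps = partition_uncertainty(rich_fact)
    unc_summary = summarize_uncertainty(unc_maps)

    # --- conservation ----------------------------------------------------
    binary_by_species = {sp: s.map_set.binary
                         for sp, s in species_results.items()}
    pa_report = conservation.pa_effectiveness(binary_by_species, pa_ids)

    ft = {sp: s for sp, s in species_results.items()
          if s.truth.habitat == "FT"}
    guild_totals = {g: sum(1 for s in ft.values() if s.truth.guild == g)
                    for g in GUILDS}
    guild_totals = {g: n for g, n in guild_totals.items() if n > 0}
    guild_rich = {
        sid: {g: assemblage.stack_richness(
            [s.map_set.binary[sid] for s in ft.values()
             if s.truth.guild == g], sid).counts
            for g in guild_totals}
        for sid in stacks
    }
    stable = conservation.stable_area_sweep(
        guild_rich, guild_totals, pa_mask, deforest,
        thresholds=config.guild_thresholds,
        cell_area_km2=grid.cell_area_km2)

    result = PipelineResult(
        config=config, stacks=stacks, selection=selection,
        occurrences=occurrences, species=species_results,
        excluded=excluded, range_table=range_table, census=census,
        guild_summary=guild_summary, richness=richness,
        uncertainty_maps=unc_maps, uncertainty_summary=unc_summary,
        pa_report=pa_report, stable=stable, pa_mask=pa_mask,
        pa_block_ids=pa_ids, deforest_mask=deforest)

    if out_dir is not None:
        _write_artifacts(result, Path(out_dir), write_rasters)
    return result


def _write_artifacts(result: PipelineResult, out: Path,
                     write_rasters: bool) -> None:
    from . import io as sio
    out.mkdir(parents=True, exist_ok=True)
    sio.write_occurrences(out / "occurrences.csv", result.occurrences)
    eval_rows = []
    for sp, s in result.species.items():
        for r in s.eval_records:
            eval_rows.append({"species": sp, "algorithm": r.algorithm,
                              "pa_set": r.pa_set_id, "repeat": r.repeat_id,
                              "tss": r.tss, "roc": r.roc_auc,
                              "sensitivity": r.sensitivity,
                              "specificity": r.specificity,
                              "cutoff": r.cutoff,
                              "retained": r.key in set(s.retained_keys)})
    pd.DataFrame(eval_rows).to_csv(out / "evaluation.csv", index=False)
    result.range_table.to_csv(out / "range_change.csv", index=False)
    result.census.to_csv(out / "loss_gain_census.csv", index=False)
    result.guild_summary.to_csv(out / "guild_area_summary.csv", index=False)
    result.pa_report.to_csv(out / "pa_report.csv", index=False)
    result.stable.as_frame().to_csv(out / "stable_areas.csv", index=False)
    summary = result.summary()
    summary["digest"] = result.summary_digest()
    summary["seed"] = result.config.seed
    (out / "summary.json").write_text(json.dumps(summary, indent=2))
    if write_rasters:
        grid = next(iter(result.stacks.values())).grid
        for sp, s in result.species.items():
            d = out / "maps" / sp
            d.mkdir(parents=True, exist_ok=True)
            for sid in s.map_set.maps:
                sio.write_ascii_grid(d / f"{sid}_consensus.asc",
                                     s.map_set.maps[sid], grid)
                sio.write_ascii_grid(d / f"{sid}_binary.asc",
                                     s.map_set.binary[sid].astype(float),
                                     grid)
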