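# Methods

## Study design

The package implements the ensemble stacked-SDM protocol on a planar,
equal-area grid. Cells are squares of `cell_size_km` (default 10 km), so
each cell covers exactly 100 km² and all area accounting is exact integer
arithmetic times a constant. A geographic CRS is deliberately not used: the
analyses treat every cell as equal-area, and a planar synthetic world
reproduces that accounting without projection error. Coordinates are km
from the grid's south-west origin; a point on a shared cell edge belongs to
the cell on the upper/right side (half-open convention).

Seven climate scenarios are configured by default: `current` plus three
emissions pathways at two horizons (`rcp26/rcp60/rcp85 × 2050/2070`).
Future stacks are the current stack with an additive shift on the first
climate axis of 0.8–2.2 within-grid standard deviations, increasing with
pathway severity and horizon. Only the first axis is shifted by default;
`apply_scenario_shift` accepts arbitrary per-layer deltas and linear
spatial ramps.

## Synthetic world

**Climate.** Each layer is Gaussian-filtered white noise (filter sigma =
`autocorr_scale_km`, default 80 km), standardized to zero mean and unit
variance over the grid. This gives smooth, spatially autocorrelated
surfaces with roughly Gaussian marginals. No attempt is made to mimic real
bioclimatic covariance structure; layers are approximately independent,
which makes the collinearity-pruning step testable by construction (noisy
copies are added where redundancy is required).

**Species truth.** Occurrence probability is a Gaussian-bump logistic
niche, `p = logistic(a + Σ_v w_v·exp(−(x_v−opt_v)²/2β_v²))`, with the
intercept `a` calibrated by Brent root finding so the grid-mean of `p`
equals the prevalence target (±10⁻⁴, well inside the 0.01 contract; an
unreachable target raises a calibration error). The community generator
draws niche weight in 10–16 and breadth in 0.8–1.2 standard deviations of
the (standardized) climate. These values put the species in a strongly
climate-determined regime: the truth-score ROC ceiling (scoring cells by
`p` itself) is ≈ 0.88 at prevalence 0.2, which is the informative regime
the recovery analyses require. Forest (FT) species receive a first-axis
optimum in the 5–35% band of the current layer range (cool-adapted),
open-area (OAV) species in the 70–95% band (warm-adapted); guilds
(FR/IN/NE/OT) are assigned round-robin. Warming therefore has a known
qualitative signature — FT contraction, OAV persistence or expansion —
against which projections are checked.

**Sampling.** Presences are drawn with replacement with probability
proportional to `p(cell) × bias(cell)` and jittered uniformly within the
cell; exact duplicates are removed. The default bias surface is a constant
floor plus Gaussian effort hotspots, emulating roadside/settlement
observer bias. The generator does **not** emulate detection failure,
taxonomic error, or temporal structure, so passing recovery tests bounds
performance under idealized (if biased) sampling only.

**Masks.** Protected-area blocks are disjoint random rectangles of ≥ 10
cells (≥ 1,000 km² at default resolution), 13 by default. Deforestation is
thresholded smoothed noise covering the requested fraction of non-PA cells
(quantile thresholding makes the achieved fraction exact up to ties).

## Models

Both algorithm families operate on linear + quadratic terms of each
retained predictor, standardized by training mean/SD. Fits are authored
penalized binomial likelihoods optimized with L-BFGS-B:

* **GLM** — ridge penalty 10⁻⁶ (numerical stabilizer only; effectively
  maximum likelihood).
* **Maxent-like** — L1 penalty via the positive/negative coefficient
  split (β = u − v, u,v ≥ 0), which keeps the objective smooth. Penalty
  strength is chosen from {0.001, 0.01, 0.1, 1} by log-likelihood on an
  internal 20% holdout. This is the penalized presence–background
  logistic equivalent of maximum entropy; hinge/product/threshold
  features are out of scope, so it is an explicit approximation rather
  than a bit-compatible Maxent.

Two safeguards address extrapolation, the dominant failure mode when
projecting to shifted climates:

1. **Concavity constraint** — quadratic coefficients are bounded ≤ 0, so
   every single-variable response is concave on the logit scale (unimodal
   or monotone, never U-shaped). Without the bound, species whose optimum
   sits at the edge of the sampled climate get convex fits whose outer arm
   rises, projecting spurious range *gains* under strong warming. The
   constraint encodes the same unimodal-niche assumption that motivates
   quadratic features in the first place.
2. **Clamping** — at prediction time each input variable is clamped to its
   training range, holding responses at their boundary value outside the
   calibrated domain (the standard Maxent projection behaviour).

Pseudo-absences are sampled at cell resolution, uniformly and without
replacement from cells containing no presence, at cell centers. Requesting
more background cells than exist is an explicit error; the pipeline
default of 400 presence draws per species keeps 10× background sampling
feasible on the default 60×60 grid after thinning (10 km thinning caps
retained records near one per cell, and 10× that must fit in the non-
presence pool).

## Evaluation and ensemble

Splits are stratified by class, 80/20, repeated 10 times, with both
classes guaranteed in both partitions (bounded resampling, then error).
TSS is maximized exactly over all distinct observed scores as cutoffs
(prediction positive iff score ≥ cutoff; ties broken toward the lowest
cutoff), so the identity TSS = sensitivity + specificity − 1 holds exactly
at the reported optimum. ROC AUC is computed by midrank Mann–Whitney U
(ties count ½). The elimination rule keeps replicates with TSS ≥ 0.5 —
boundary inclusive, resolving the ambiguity at exactly 0.5 in favour of
retention.

Committee averaging binarizes each retained member at its own held-out
cutoff and averages the votes, so consensus values are exact multiples of
1/m. One ensemble-level cutoff per species — the TSS maximizer of
consensus scores at pooled held-out samples (each evaluation partition
contributes once per repeat) — binarizes all seven scenario maps; future
scenarios have no evaluation data, so no per-scenario alternative exists.
Per-algorithm committee maps are built the same way from each algorithm's
retained members for the uncertainty factorial.

## Assemblage, uncertainty, conservation

Richness is the per-cell sum of binary maps. Range change is
(future − current)/current area; −1 means no suitable habitat remains,
kept as a distinct census category. Loss/gain censuses count a species in
every threshold bin it meets (20/50/90/100%), so bins are nested by
construction. Quartiles use linear interpolation.

Uncertainty is a per-cell two-way main-effects decomposition of the
2 (algorithms) × 6 (future scenarios) richness table: proportions are
SS_factor/SS_total, the single-replicate interaction is reported as
residual, and cells with zero total SS are masked as undefined. The
current scenario is excluded from the factorial. On synthetic data the
scenario factor dominates: both algorithm families share one feature
expansion and agree closely, so between-algorithm variation is small.
Field studies with heterogeneous algorithm suites typically find the
opposite ranking; the partition itself is agnostic.

PA effectiveness marks a species present in a block if ≥ 1 presence cell
falls inside it; lost + retained = current richness by construction, and
percent loss uses the no-turnover basis (gains are reported separately).
The stable-area sweep qualifies a cell at threshold X iff it holds at
least ⌈X%·total⌉ species of **every** configured guild (ceiling keeps the
integer richness requirement conservative), calls it stable iff it
qualifies in ≥ 6 of 7 scenarios, and partitions stable cells with
precedence protected > deforested > intact-unprotected. All four guild
classes are required by default; the set is configurable. Fine
deforestation masks are aggregated by majority rule (fraction ≥ 0.5),
with exact grid nesting required.

## Numerical and design choices

* Thinning is greedy in seed-controlled random order; the paper-style
  minimum-distance guarantee is exact and idempotent, but the retained
  set depends on the visit order (no maximal-subset claim).
* Collinearity pruning repeatedly drops the lower-priority member of the
  worst-offending pair (default priority = layer order); zero-variance
  layers are dropped up front since r is undefined.
* Correlation screening uses current-scenario values only (configurable
  by passing a different stack).
* The manual removal of implausible outlier records that real-data
  workflows apply by expert opinion is replaced by an optional
  distance-from-centroid quantile filter, off by default.
* All stage and per-species seeds derive from one root seed through
  `numpy` generator streams; reruns are byte-identical (verified on the
  summary digest).
* Default problem sizes — 20 species, 60×60 grid, 400 presence draws,
  5 climate layers — are the package's reference study; the full run
  completes in well under a minute on one core.

## Known limitations

* Only two algorithm families; the uncertainty factorial is accordingly
  narrow (see above).
* The maxent-like model omits hinge/product features, so sharp niche
  edges are smoothed.
* Presence-only truth with uniform pseudo-absences means reported
  sensitivity/specificity describe discrimination against background,
  not against true absences.
* Stable-area classification assumes static PA and deforestation masks
  across scenarios.
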