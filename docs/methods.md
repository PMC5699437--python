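# Methods

`beediv` estimates how three facets of bee community diversity — species
(SD), functional (FD) and phylogenetic (PD) — respond to land-use class,
cropland use-intensity and human population density (HPD), and projects
the fitted responses over a gridded landscape relative to an uninhabited
semi-natural baseline. This note documents the model, the algorithmic and
numerical choices, and what the synthetic test system does and does not
establish.

## Diversity framework

All three facets are computed as Rao's quadratic entropy

  Q = Σᵢⱼ dᵢⱼ pᵢ pⱼ,

the expected dissimilarity between two individuals drawn at random from a
site, where pᵢ are relative abundances and dᵢⱼ ∈ [0, 1] a species
dissimilarity, transformed into an effective number of species

  E = 1 / (1 − Q),

the count of equally abundant, maximally distinct species with the same
entropy. The facet is carried entirely by the distance matrix:

* **SD** — dᵢⱼ = 1 for i ≠ j; Q is then the Gini–Simpson index and E the
  inverse Simpson index.
* **FD** — Gower dissimilarity over mixed trait types: range-normalized
  absolute differences for continuous traits, 0/1 mismatch for
  categorical, averaged over traits, then square-rooted. The square-root
  correction makes the matrix Euclidean-embeddable (verified by the
  doubly centred Gram-matrix eigenvalue test). Continuous ranges are
  taken over the **full species pool**, not per community, so distances
  are comparable across sites.
* **PD** — half the cophenetic distance between tips (the distance to
  the most recent common ancestor on an ultrametric tree). Because E
  requires Q < 1 and raw cophenetic distances are unbounded, the
  half-cophenetic matrix is rescaled by its maximum. This rescaling is a
  necessary interpretation: without it the transform is undefined. PD is
  averaged over a sample of trees (default 100 in full runs) that vary
  in where species missing from the phylogeny were grafted; Q is
  averaged across trees **before** the transform to E (averaging E
  instead is available via `site_diversity(average="E")`; at the small Q
  spreads produced by grafting variation the two differ negligibly).

Abundances are first corrected for unequal sampling effort assuming
recorded abundance grows linearly with effort: within each study, every
site is rescaled to the study's maximum effort. Relative abundances —
and hence Q — are invariant to this per-site rescaling; the correction
matters wherever absolute abundances are compared.

## Trait imputation

Missing trait values are imputed with an iterative random-forest scheme
(missForest): initialize missing cells at the column mean/mode, then
cycle over incompletely observed traits in order of increasing
missingness, regressing each on all other traits **plus phylogenetic
eigenvectors**, and stop when the aggregate change in imputed values
first increases (returning the previous iterate) or after 10 passes.
Forests use 100 trees and library-default split parameters. Accuracy is
reported from out-of-bag predictions as NRMSE (continuous; RMSE divided
by the standard deviation of the observed values) and PFC (proportion of
falsely classified categorical cells); both run from 0 (good) to ~1
(poor). Observed cells are never modified; species with no trait data at
all are imputed entirely from the eigenvectors plus the other species'
trait structure.

Phylogenetic eigenvectors are the principal-coordinate axes of the
half-cophenetic distance matrix. The number of axes defaults to those
explaining 60% of the (positive) eigenvalue mass, capped at 30 — enough
to encode broad tree position without letting the predictor count
approach the species count.

Because phylogeny informs the imputation, FD computed from imputed
traits is pulled toward PD; this bias is inherent to the approach and is
one reason both facets are reported.

## Completing the phylogeny

Species absent from the tree are attached within their genus clade
(fallback: family clade) at a point drawn uniformly over the clade's
total branch length, with the pendant length chosen to preserve
ultrametricity. Repeating this n times yields a tree sample whose spread
propagates placement uncertainty into PD. This is a deliberate,
documented simplification of Bayesian birth–death polytomy resolution:
it preserves the robustness strategy (averaging over many completions)
while replacing MCMC tree inference, and no equivalence with the
Bayesian placement prior is claimed.

## Mixed models

Each facet is modelled with a Gaussian linear mixed model: fixed effects
for land use (six collapsed levels, reference *semi-natural*), centred
log1p HPD, centred log1p distance to roads, subregion, and the two-way
interactions of land use with the continuous pressures; random
intercepts for study and for block nested in study. SD (the effective
number) is ln-transformed; FD and PD are modelled on the identity scale.
Centring constants are stored in the fitted object so projection applies
identical transforms.

* **Random structure** is chosen by AIC among REML fits sharing the full
  fixed structure, over {study intercept} × {± block intercept} ×
  {± random HPD slope within study}. The random slope is on the
  continuous HPD covariate rather than the 6-level land-use factor: a
  categorical random slope adds a 6×6 covariance block that is
  rank-deficient with ~10 studies and fails or degenerates in
  essentially every fit, making the AIC comparison meaningless.
  statsmodels reports no AIC under REML, so AIC is computed directly as
  −2·logLik + 2·(fixed + covariance parameters). Singular fits
  (variance components at zero) are retained in the candidate set but
  flagged, and non-singular candidates are preferred.
* **Fixed structure** is simplified backwards with likelihood-ratio
  tests on ML fits: at each step the least significant droppable term is
  removed while its deletion p-value exceeds 0.05, interactions before
  their main effects (marginality is never violated). 0.05 is the
  conventional threshold of the stepwise methodology.
* **Inference.** Type II analysis-of-deviance tables test each term
  against the model containing every term not including it. Confidence
  intervals are a **parametric** bootstrap — responses are simulated
  from the fitted model, respecting the nested study/block structure,
  and the model refitted — because case resampling would break that
  structure; a coefficient is significant when its percentile interval
  excludes zero. Marginal R² is the fixed-effect variance over the total
  (fixed + random + residual) variance, with random-slope contributions
  averaged over the observed covariate values. Collinearity is checked
  with determinant-ratio generalized VIFs; residual spatial
  autocorrelation with Moran's I under inverse-distance weights and a
  permutation null.
* The final reported fit is by REML; ML is used only for fixed-effect
  comparisons.

**Known limitation.** With ~10 studies, ML likelihood-ratio tests for
fixed effects are mildly anticonservative (per-term type I error ≈ 7%
rather than 5% in our simulations). Backward selection therefore retains
a truly null variable slightly more often than the nominal rate
suggests; users with few groups should treat borderline retained terms
with caution.

## Projection

For every grid cell the fitted fixed effects predict each facet at the
cell's HPD and subregion for each land-use class present, and the cell
value is the **area-fraction-weighted mean on the response
(effective-number) scale** — back-transforming the SD model by exp
before weighting. Class fractions come from the land-use layers: primary
and secondary vegetation pool into semi-natural; the cell's whole
cropland fraction is assigned to its reclassified intensity level
(light/moderate/intensive → low/medium/high; cells containing cropland
but carrying a non-cropland intensity class are classed **low**, which
keeps projected losses conservative); plantation forest has no model
level and is renormalized away. Random effects are excluded: maps
describe the typical community, not any particular study. No
retransformation-bias correction is applied to the ln-scale SD model —
under homoscedasticity the correction cancels in the prediction/baseline
ratio.

The baseline is the prediction for a cell entirely of semi-natural
vegetation with raw HPD = 0, evaluated per the cell's own subregion; the
map reports 100 × prediction/baseline, so baseline-equivalent cells are
exactly 100%. For the multiplicative SD model the subregion intercept
cancels in this ratio; for FD/PD it does not, which is why a subregion
layer is required. Country summaries are means over defined cells with a
standard error from spatial variation only (population SD over cells
divided by √n, matching the convention of the packaged country table).

## Spatial mismatch

Projected FD and PD (percent of baseline) are each regressed on
projected SD by OLS over all defined cells jointly — one continental
relationship, not per-country fits — and the residual maps show where
losses in one facet are more (negative) or less (positive) severe than
SD losses predict. A second-stage OLS between the two residual maps
isolates the FD-vs-PD mismatch; the default regresses the PD residuals
on the FD residuals (`direction="pd_on_fd"`, configurable, since the
choice of response is a convention).

## Synthetic study system

The generator produces the full study structure with known ground truth:

* **Phylogeny** — a birth–death tree (dendropy) over 2–n species;
  genera and families are maximal clades (≤5 and ≤25 tips), so taxonomy
  is consistent with the tree, as grafting requires. Terminal branches
  absorb floating-point drift so trees are ultrametric to 1e-8.
* **Traits** — Brownian motion on the tree for continuous traits and a
  symmetric continuous-time Markov chain for categorical ones; the
  default battery mimics bee trait data (body size, flight season, diet
  breadth, nesting strategy, sociality).
* **Sites** — studies of blocked sites (blocks of 5), land uses drawn
  from a mix dominated by medium/high-intensity cropland, HPD and
  distance to roads log-normal (HPD median 50 persons/km²), coordinates
  jittered around study centres, integer sampling efforts 1–5.
* **Communities** — the site's expected ln effective species number is an
  explicit linear predictor: baseline (ln 8) + land-use effect (pasture
  −0.39, medium cropland −0.50, high cropland −0.48, low cropland −0.10,
  urban −0.06 on the log scale) + HPD slope + study/block random effects
  (SDs 0.25/0.10) + residual (SD 0.30). The realized abundance profile
  (one dominant species, the rest equiabundant) matches the target
  inverse Simpson index **exactly**, so the fitted model is exactly
  true and recovery tests probe the estimator, not distributional slack.
  Which species occur is driven by a phylogenetically correlated
  sensitivity score (correlation 0.6 by default), so harsher land uses
  remove related species together and FD/PD responses decouple from SD.
* **Rasters** — spatially autocorrelated land-use fraction fields
  normalized to sum to one per cell, an intensity-class layer, a
  log-normal HPD surface, and contiguous countries from a Voronoi
  partition of random seed points, with subregions derived from
  countries. Layers are stored as plain-text ESRI ASCII grids, one file
  per layer with a shared geotransform.

What the synthetic system does **not** emulate: real geography or
taxonomy, detection/sampling error in abundances (effort enters only as
a deterministic linear factor), spatially autocorrelated residuals,
abundance distributions of real communities (the dominant-plus-evens
profile is a construction, not a biological claim), or imbalance between
study designs beyond the block structure. Passing tests therefore show
that the estimators recover known structure under the stated model, not
that the model is adequate for any particular real dataset.

## Problem sizes and numerical conventions

Tests and the acceptance script run at deliberately modest sizes chosen
to make the Monte-Carlo checks informative: 60-species pools (120 for
imputation scoring, where masked-cell counts set the resolution of the
comparison), 10 studies × 50 sites for parameter recovery, 30 × 40
rasters with 5 countries, 5–25 grafted trees. Full analyses would use
the 100-tree PD sample and 1000 bootstrap draws; both are plain
parameters. All randomness flows from one master seed through
`numpy.random.SeedSequence` fan-out, so every stage is independently
reproducible; rerunning the pipeline with the same seed reproduces every
artifact byte-for-byte (verified via SHA-256 in the run manifest).
Degenerate inputs fail loudly: zero-range continuous traits are excluded
from Gower with a warning, Q ≥ 1 (an unscaled distance matrix) raises,
rank-deficient fixed-effect designs raise before fitting, and a
non-positive baseline aborts the relative map.
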