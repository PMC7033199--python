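# Methods

`threatgrid` implements a spatial analysis of the drivers of threatened
species richness: random-forest regressions of per-cell threatened
richness on total species richness plus environmental and human-impact
covariates, evaluated by spatially blocked cross-validation, with a
randomization variable-importance statistic, category-level
repeated-measures comparison, partial-dependence response curves, and a
data-deficient sensitivity analysis. A seeded synthetic-world generator
supplies gridded inputs with known (planted) structure so every stage
can be validated end to end.

## The statistical model

Let `y_i` be the threatened species richness of grid cell `i` (count of
species with Red List status VU, EN or CR present in the cell) and
`x_i` the covariate vector: total species richness `S`, environmental
covariates `E` (climate, topography, land-cover diversity, insularity,
paleo-climate stability) and human-impact covariates `H` (human land
use, influence index, protection, land-cover change, invasive species).
Random-forest regressions (scikit-learn `RandomForestRegressor`,
bootstrap on, unlimited depth) approximate `E[y | x]` without
distributional or linearity assumptions. Three model tiers are fitted:

1. **richness-only** — `y ~ S` alone; per-cell mean residuals across
   the fold models map *excess* imperilment (where threat is higher
   than the species pool predicts);
2. **full** — `y ~ S + E + H`, globally, per taxon group and per
   zoogeographic region;
3. **paired response models** — `y ~ S + E + H` for threatened richness
   and `S ~ E + H` for total richness, fitted separately to contrast
   the functional responses of the two quantities.

### Spatial blocking

Gridded richness is strongly spatially autocorrelated, so random
train/test splits overstate skill. Cells are therefore grouped into
sampling units — each non-contiguous patch of an ecoregion is one unit
— and units into `k = 10` blocks such that (a) every cell of a unit
shares its block, (b) each block's covariate means sit close to the
global means, and (c) each block spans (most of) each covariate's
range. Cross-validation trains on 9 blocks and tests on the held-out
block; performance is `R² = 1 − SSE/SST` on the held-out cells (a
squared-correlation variant is available via `r_squared(...,
method="corr")`).

The grouping algorithm (the published analyses this mirrors cite an
external blocking tool without algorithmic detail, so only the stated
properties are enforced): a greedy size-ordered construction seeds the
`k` largest units into distinct blocks and places the rest to minimise
a global objective, followed by seeded simulated annealing over
single-unit reassignments and deterministic move/swap polishing, with
two restarts. The objective combines

- mean-square deviation of block covariate means from global means,
- a worst-deviation term (weight 30) — the contract is on the largest
  departure, not the average,
- a range-coverage shortfall term (weight 100): each block should span
  ≥ 95% of each covariate's central 90% range (5th–95th percentiles),
- a block-size imbalance penalty (weight 0.3) with a soft cap at 1.5×
  the average block size.

Coverage is judged against the central 90% range — the same range
convention the response curves use — because the literal min–max range
of a Gaussian field is set by single extreme cells that can only ever
belong to one block (on the default world some 1% tails are reachable
by only 6 of ~90 units, making a min–max coverage demand infeasible for
any grouping). On default worlds the optimiser delivers worst
block-mean deviations of ~0.2 SD (contract: < 0.25 SD) and worst
coverage ~0.92 (contract: ≥ 0.90).

### Hyperparameter tuning

Following the grid the analysis prescribes, the number of predictors
per split `m ∈ {1, 2, 3}` and tree count `nt ∈ {1000, 1500, 2000, …}`
are tuned per fold: start at `nt = 1000`, add 500 trees, keep adding
while each increment improves held-out R² by more than 1% — read as
*relative* improvement (>1% of the current R²); an absolute-point
reading is available via `improvement_mode="absolute"`. The winning
`(m*, nt*)` maximises the mean held-out R² across folds over *accepted*
configurations (a fold that stopped early contributes its final
accepted R² to larger-`nt` candidates), ties to fewer trees, then
smaller `m`. When the current R² is ≤ 0, the relative gain is computed
against `max(|R²|, 1e-12)`.

### Randomization variable importance

For a fitted model with predictions to the full data set,

    VI = sqrt((MSE_rand − MSE_obs) / MSE_obs)

where `MSE_obs` uses the observed covariates and `MSE_rand` the data
with the focal covariate's column randomly permuted (a uniform
permutation of observed values, preserving the marginal). Repeats
(default 1000; library callers may scale down) are averaged; when a
permutation happens to *reduce* the MSE — routine for null covariates —
the radicand is negative and the repeat is clamped to VI = 0 (the count
of clamped repeats is reported). The statistic is computed per
covariate per fold model; summaries use the median and IQR across
models, and fold models with held-out R² < 0.25 are excluded before
importance is computed (regional models mainly).

Because predictions are made to the full data set, `MSE_obs` is partly
in-sample and small; permuting *any* covariate the forest ever splits
on therefore yields a nonzero VI. Planted drivers still dominate
clearly, but null covariates carry a noise floor (VI ≈ 0.5 at the
default problem size) rather than exact zeros — a property of the
statistic as defined, not an implementation artefact.

### Category comparison

Per fold model, VI is averaged within each category (S is the single
total-richness variable) and the three category means are compared with
a repeated-measures ANOVA (`pingouin.rm_anova`, fold model as subject).
Post-hoc pairwise contrasts E−H, S−H, S−E are paired-difference
normal-approximation z tests (estimate = mean paired difference, SE =
SD/√n) with single-step Šidák family-wise adjustment across the three
contrasts. With zero-variance differences the contrast is reported as
z = 0, p = 1.

### Response curves

Partial dependence follows the held-at-reference profile construction:
a single synthetic row with every non-focal covariate at its mean (mode
for covariates registered as categorical, ties to the smallest value),
the focal covariate swept over 50 equally spaced points between its 5th
and 95th percentiles; each fold model predicts at each point and the
curve reports the across-model mean and SD. Classical full-data partial
dependence (averaging over observed rows) is available via
`full_data=True`. Paired curves fit the threatened-richness and
total-richness ensembles with covariate sets differing only by the
total-richness column and share the evaluation grid per variable.

### Data-deficient sensitivity

Per cell, a Binomial(dd, p) draw of the DD species is reclassified as
threatened for p ∈ {0, 0.5, 1} (other p allowed but flagged), models
are refitted and importance recomputed. DD species are already counted
in total richness (statuses partition the species list), so totals are
unchanged. All seeds derive from the master seed independently of p, so
p = 0 reproduces the base analysis bit-for-bit.

## The synthetic world

The generator emulates the statistical structure the analysis assumes —
not real geography, taxonomy or range-size distributions.

- **Lattice**: equal-area cells (default 60×120, cell area 3091 km², a
  0.5° Behrman cell); no map projection is implemented.
- **Land mask**: a Gaussian-smoothed white-noise field plus
  `n_landmasses` Gaussian bumps, thresholded at the quantile giving
  `land_fraction` (default 0.3). Land masses are the 8-connected
  components (4-connectivity available; adjacency is a convention, not
  given by the science).
- **Ecoregions / regions**: nearest-seed tessellation of land cells
  into `n_ecoregions` (default 40) ecoregions; the first `n_regions`
  (default 8) ecoregion seeds double as region seeds, so regions are
  unions of ecoregions and every region spans at least one.
- **Covariates**: 15 layers (9 E, 6 H), each independent smoothed white
  noise standardised over land cells; the designated pair
  (mean temperature, temperature seasonality) is mixed through sample
  Gram–Schmidt so its Pearson correlation over land cells is exactly
  0.85, emulating the strong collinearity of real bioclim layers. The
  smoothing length scale (`autocorr_range`, default 1.5 cells ≈
  correlation range 3 cells) is deliberately below the typical
  ecoregion patch diameter (~7 cells): covariates must vary *within*
  sampling units, as climate does within real ecoregions — with
  near-constant fields per patch, balanced blocking is mathematically
  impossible at this world size.
- **Species counts**, per taxon (amphibians, reptiles, birds, mammals):
  total ~ negative binomial (Poisson–gamma, dispersion `k = 10`) with
  log-mean = taxon intercept + planted baseline responses; a
  multinomial split of the total into threatened / data-deficient /
  other, with threat probability `sigmoid(base logit + planted
  effects)` applied to the assessed fraction and `dd_rate = 0.10`, so
  `threatened + dd ≤ total` cell-wise. Default taxon mean totals
  (20/25/120/60 per cell) echo the relative sizes of the four global
  species pools; the base threat logit −1.73 puts ~1 in 6 assessed
  species threatened, matching the share of threatened terrestrial
  vertebrates. The combined layer is the cell-wise sum of the four
  taxa. True expected values are returned alongside the counts for
  oracle tests.
- **Effect forms** on the standardised covariate scale: `linear±` (±s·z),
  `unimodal` (s·(1−z²)/2, peak at z=0), `asymptotic`
  (s·(1−exp(−(z+2)/1.5)), saturating), `threshold` (s·1[z>0]). A
  saturating form has roughly ¼ the SD of a linear form per unit
  multiplier, so comparable-strength designs scale its multiplier
  accordingly (the planted-driver test world uses 1.2 linear / 4.0
  asymptotic / 1.0 linear ≈ 1 SD each on the logit scale).
- **Default recipe** (`default_effect_spec`): total richness responds
  to mean temperature (+), land-cover diversity (+) and human land use
  (unimodal); threat responds to elevational heterogeneity (+, E),
  annual precipitation (asymptotic, E) and human land use (+, H) — so S
  dominates importance, E outranks H, and human land use shows the
  classic contrast of monotone-positive threatened vs unimodal total
  response.

What passing tests on this world do **not** show: recovery on real
data with measurement error, sampling bias, non-stationary
autocorrelation, realistic range-size distributions or genuinely
unknown functional forms. The generator's functional forms are testing
devices, not estimates of any real generative process.

## Numerical and design choices

- One master seed; per-stage child seeds derived via
  `SeedSequence([seed, stage])`, so stages are independently
  reproducible and all derived seeds stay below 2³¹.
- Cell geometry for rasterization: cell `(row, col)` is the half-open
  rectangle `[col, col+1) × [row, row+1)` in units of `cell_size`,
  0-based row-major ids; polygons touching a cell boundary count as
  present (presence on *any* intersection).
- Majority-coverage labels break ties to the smallest label id.
- Climate-stability z-transform is pooled over the full cell×time stack
  (distances comparable across cells); per-snapshot standardisation via
  `pooled_z=False`.
- `r_squared` requires non-constant observations and ≥ 2 points;
  `variable_importance` refuses a perfect model (MSE_obs = 0).
- Regional models reuse the global block labels restricted to the
  region's cells; regions with < 10 cells are excluded before fitting,
  folds with empty test sets or < 20 training cells are skipped, and a
  region whose fold models all fall below the R² floor is reported as
  having no valid models.
- Forest defaults beyond `(m, nt)`: unlimited depth, bootstrap on,
  `min_samples_leaf = 5` — the regression default (`nodesize = 5`) of
  the reference R `randomForest` implementation, which scikit-learn's
  own default of 1 does not match; interpolating single-observation
  leaves would inflate the randomization importance of null covariates.
  `n_jobs = 1` for determinism.

## Problem sizes

Library defaults follow the analysis scale (`nt ≥ 1000` trees, 1000
importance repeats). The test suite and `scripts/acceptance.py` run the
full pipeline on one 60×120 world (~2160 land cells, 40 ecoregions,
~90 sampling units) with `nt = 1000`, `m = 3` and 10 importance repeats
— chosen so the whole suite completes on a single CPU while the
planted-driver ranking remains far outside Monte-Carlo error; the DD
sensitivity baseline check, which is about bit-identity rather than
statistical power, uses deliberately small forests (nt = 60).

## Known limitations

- The blocking optimiser is a heuristic; it enforces the stated
  properties on the worlds tested but offers no optimality guarantee,
  and its runtime grows with unit count (~10 s at ~90 units).
- VI's full-data evaluation mixes in-sample and out-of-sample error;
  rankings are meaningful, absolute VI magnitudes depend on forest
  overfit (see above) and are not comparable across data sizes.
- The Šidák single-step adjustment assumes contrast independence; with
  three mutually dependent contrasts it is slightly conservative.
- `reclassify_dd` draws cell-wise binomials, not species-list-wise
  reclassification, so the same nominal species may be resolved
  differently in different cells.
- Raster output is plain single-band TIFF (row-major, north-up) plus
  CSV; no CRS metadata is written and no reprojection is provided —
  inputs must already share the analysis grid.
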