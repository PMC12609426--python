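# Methods

## The reconstruction problem

Satellite retrievals of solar-induced chlorophyll fluorescence (SIF, in
W m⁻² μm⁻¹ sr⁻¹) from sparse-sampling spectrometers cover only narrow
ground swaths on any given day, while BRDF-corrected 7-band surface
reflectance is available daily and wall to wall. `sifmstws` learns the
mapping reflectance → SIF and uses it to predict a daily, gap-free SIF
raster on a 0.05° grid. The mapping is not universal: it changes with
vegetation type, location and phenological stage. The package therefore
trains a *fleet* of regressors, one per (day-of-year, sub-biome stratum)
pair, using Moving Spatial–Temporal Window Sampling (MSTWS).

## Preprocessing

Footprint soundings carry daily-corrected SIF at 757 nm and 771 nm and a
QC flag. Processing is:

1. **QC screen** — keep rows whose flag is in the allowed set (default `{0}`).
2. **Cross-band combination** — `sif_daily = 0.5·(sif_757 + 1.5·sif_771)`.
   For independent band noise of variance σ² the combined residual
   variance is `0.25σ² + 0.25·(1.5)²σ² = 0.8125σ²`; in the synthetic world
   the 771 nm band carries exactly 2/3 of the 757 nm signal, so the
   combination is also an exact inverse at zero noise.
3. **Five-nearest-neighbor smoothing** —
   `sif_smoothed = (1/5)·Σ sif_daily(i)` over the five nearest same-date
   footprints by great-circle distance, target excluded (a configuration
   switch includes it). Smoothing five i.i.d. values divides the noise
   variance by 5. Footprints with fewer than five neighbors within
   `max_radius` (default 0.1°) are dropped rather than partially averaged,
   preserving the variance-reduction guarantee; renormalized partial
   averaging is available as a switch. Ties in distance break on footprint
   id for reproducibility.
4. **Feature matching** — each footprint's feature vector is the unweighted
   mean of the reflectance pixels whose centers fall within the footprint
   radius (default 0.03°, i.e. the containing cell at synthetic scale);
   uncovered footprints are dropped and reported.

Rows are then labeled with DOY (1–365; February 29 maps to DOY 60 and later
leap-year days shift back by one so a calendar date keeps one DOY in every
year) and with the sub-biome stratum of their grid cell; rows on
non-vegetated or unmapped cells are excluded.

## Stratification

IGBP land-cover classes map to seven biome groups (NF, EBF, DBF, SHR, SAV,
GRA, CRO); groups split geographically into 19 model domains: NF/DBF/SHR/
SAV/GRA by hemisphere (lat ≥ 0 is NH — the boundary must close on one
side), EBF by Amazon/Congo/SE-Asia regions, CRO by six continents. Mixed
forest joins the DBF group (closest structural analogue); wetlands carry no
model ID; water, urban, snow/ice and barren cells are masked out. Region
membership comes from user polygons (GeoJSON/shapely) or, in synthetic
mode, from a region-code raster emitted by the generator. Both the mixed-
forest and mosaic-cropland mappings are overridable.

## MSTWS sampling

For target DOY *d* the sample pool is the 16-day window
{d−7, …, d, …, d+8}, wrapped on a 365-day circle (DOY-1 models need winter
samples), pooled across all available years, restricted to the stratum.
Pools above 5000 rows are capped by a seeded uniform subset; pools at or
below 1000 rows are skipped (recorded in the registry); used pools split
70:30 into training and validation partitions. The cap is applied before
the split. All of cap, floor, ratio and window are configurable; the
defaults are the method's published operating point.

## Model fleet

Three regressor families compete: gradient-boosted trees
(`HistGradientBoostingRegressor`), random forest, and a feed-forward
network (standardized inputs). Hyperparameters are selected per model by
k-fold cross-validation (default 5 folds) over small declared grids, scored
by mean CV R²; ties keep the earlier configuration. The family itself can
be fixed or chosen automatically (`algorithm="auto"`) from CV scores on the
largest pools; selection is global with a per-registry record of the
comparison. Each DOY additionally gets a *universal* model trained on the
combined window data of all strata.

At prediction time a (DOY, stratum) query resolves to: the exact model;
else the same-stratum model at minimal circular DOY distance (ties toward
the earlier DOY) within a configurable horizon (default 182 days,
i.e. unbounded); else the per-DOY universal model (exact, then nearest).
Per-cell provenance (source model key) is stored in the predicted grid.
Gridded prediction feeds each vegetated cell's 7 bands through its resolved
model; non-vegetated cells are nodata.

## Evaluation

* `regression_metrics`: R² = 1 − SS_res/SS_tot with observations as truth
  (a squared-Pearson variant is exposed, since the two diverge when the
  slope ≠ 1), RMSE, and the OLS slope of predictions (y) on observations
  (x) — the standard validation-scatter convention.
* `cross_biome_report`: metrics per stratum per algorithm; strata without
  validation rows or resolvable models are reported *absent*, never zero.
* `compare_strategies`: the fleet and a single universal model (all rows,
  all dates and strata pooled) are trained on the same 70% of the table and
  scored on the same 30% holdout (identity assertable by hash); the fleet's
  internal per-key split is disabled so both see identical data.
* `cross_sensor_validate`: airborne-style 755 nm SIF is divided by 1.12 (the
  known cross-wavelength magnitude offset), averaged per cell and date
  (unweighted), and paired with predicted cells. Omitting the correction
  scales the observed axis by 1.12 and therefore biases the scatter slope
  by that factor; the experiments report the ratio
  slope_corrected/slope_uncorrected, ≈ 1.12.

## The synthetic world

The generator emulates the statistical structure the method assumes while
staying deliberately non-physical:

* **Biome layout** — 12 longitudinal strips (water | NF | DBF | SHR | SAV |
  GRA | EBF | 3 × CRO | barren | wetland) crossed with the hemisphere
  split; EBF splits into three latitudinal region bands and each CRO strip
  into two continent blocks, so all 19 strata are realizable on any grid
  with ≥ 12 columns and rows on both sides of the equator. A seeded 2%
  open-water speckle exercises the mask.
* **Reflectance** — each band follows a stratum-phased annual cosine
  (phase peak DOY 196 for NH strata, 15 for SH, 280 for EBF) around fixed
  band means, plus a static texture field and optional Gaussian noise,
  clipped to [0, 1]. The texture is a function of the latitude row only and
  is *shared across strata*: two cells in different strata on the same row
  have identical noiseless reflectance. This makes the stratum signal
  contextual rather than spectral — reflectance alone cannot identify the
  stratum, which is precisely the regime where stratified modeling must
  beat a universal model. It is also the generator's main idealization:
  real biomes differ spectrally, so real-data gains from stratification
  will be smaller than in this world.
* **Latent truth** — `SIF = max(a0(s, season) + a1(s, season)·g, 0)` with
  `g = NIR − red` (band 2 − band 1). Coefficients are per-stratum,
  per-season constants drawn once per (config, seed) from configured ranges
  (a0 ∈ [0.3, 0.8], a1 ∈ [0.8, 2.0], ±35% seasonal multipliers) and are
  retrievable from the world object, giving an exact recovery oracle.
  Seasons switch at DOY 1/92/183/274; a 16-day window that stays inside a
  season sees one constant mapping, so zero-noise recovery is well-posed.
* **Footprints** — a longitudinal swath (default 12 cells wide) sweeps the
  grid once per revisit period (default 8 days), guaranteeing full coverage
  within a window; each swath cell yields 6 footprints jittered within the
  central 30% of the cell, which keeps same-cell footprints mutually
  nearest and makes five-neighbor smoothing average same-cell values.
  Band values are `S + e₁` and `(2/3)S + e₂` with independent Gaussian
  noise (scalar or per-stratum σ); a configured fraction gets failing QC.
* **Airborne samples** — dense per-cell points at 1.12 × truth plus small
  noise, for cross-sensor validation.

What passing tests on this world do **not** show: radiative-transfer
realism, orbital mechanics, cloud contamination, retrieval-physics QC
structure, spectral separability of biomes, or land-cover change. The
world is a correctness and sensitivity harness, not a simulator.

## Numerical and design choices

* Distances are great-circle central angles in degrees (haversine).
* The neighbor search uses an exact all-pairs sort for ≤ 256 same-date
  footprints and an argpartition prefilter above that; both reproduce the
  brute-force (distance, id) ordering on continuous data.
* Grid registration: EPSG:4326, cell-edge aligned at the configured NW
  corner, north-up, half-open cell intervals. Rasters serialize as Esri
  ASCII grid text (one file per band, JSON sidecar for multiband stacks).
* Every random operation derives its seed from the configured seed through
  `numpy.random.SeedSequence` spawns keyed by (DOY, stratum, purpose), so
  runs are reproducible and individual stages can be re-run in isolation;
  the pipeline stamps a config hash into its run manifest and regenerates
  only stages whose artifacts are missing or stale.
* Degenerate inputs: zero-variance targets, empty allowed-flag sets,
  sub-2-row splits, unknown IGBP codes, misaligned rasters and
  out-of-range DOYs all raise with explicit messages.

## Experiment problem sizes

The packaged experiments (`sifmstws.experiments`, also driven by
`scripts/acceptance.py`) use: a 40 × 80-cell world, two years and 12
mid-season DOYs for zero-noise recovery (~240 fitted models); ten seeded
replicates of a 20 × 60-cell single-year world, one DOY each, for the
stratified-vs-universal comparison (the win criterion is ≥ 90% of
replicates); ≥ 10⁴ Monte-Carlo footprints/neighborhoods for the two noise
laws; and a 20 × 40-cell pipeline run executed twice for byte-level
determinism. The strategy, fallback and cross-sensor experiments fit a
single gradient-boosted configuration (200 iterations) with 2-fold CV
scoring. The zero-noise recovery experiment instead uses the framework's
network candidate trained to convergence with L-BFGS, with the activation
function in the CV grid (identity vs tanh): the evaluation demands
per-cell accuracy at the edges of the training support, where tree
ensembles plateau at their outermost leaf values (~1.2–1.5% cell error)
and tanh networks can wobble off the thin training manifold, while on a
latent map that is linear in the bands the identity-activation network —
selected by CV on this world — recovers cells to ≲ 0.001%. These sizes
keep each experiment in the minutes range on one CPU.

## Known limitations

* The fleet trains one model per evaluated DOY; a full 365-DOY, 19-stratum
  archive (~7300 models) is a scale-out of the same code but is not what
  the packaged experiments run.
* The universal-fallback chain extends the published nearest-date rule with
  a nearest-universal step so that resolution is total whenever any model
  exists; the resolution path is recorded per cell.
* `select_algorithm` picks one family globally; per-key overrides are
  possible through `RegistryConfig.param_grid` but not automated.
* The airborne correction assumes the fixed 1.12 magnitude ratio; no
  wavelength-dependent spectral model is fitted.
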