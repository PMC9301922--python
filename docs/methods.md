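# Methods

## Problem and data model

Surface NO₂ (μg/m³) is short-lived and spatially heterogeneous; monitors are
sparse and urban-biased, while satellite spectrometers retrieve the
tropospheric NO₂ column (10¹⁵ mol/cm²) on a grid but lose roughly half of a
fine-resolution product to clouds. The package converts gappy column grids
plus covariates into complete daily surface-NO₂ fields in two stages: an
iterative tree-ensemble imputer completes the columns, then a cascade-forest
regressor maps columns and covariates to surface concentrations.

All rasters are regular lat/lon grids with cell-center coordinates and no
projection. Cell intervals are half-open per axis, closed on the cell's upper
edge and on the domain minimum, so a point on an interior boundary belongs to
the lower/left cell. Gridded stacks are CF-style NetCDF (classic format);
stations are CSV with header `station_id,city_id,lat,lon,timestamp,value`.

Station quality control drops non-finite values, hourly values outside
[0, 500] μg/m³, and runs of ≥ 6 identical consecutive hourly values at one
station (a stuck instrument). Daily means require ≥ 18 valid hours (75% of a
day). All three thresholds are configurable and reported in the QC summary;
they are pragmatic defaults for this class of network, not regulatory rules.

Area-weighted regridding factorises on regular grids into two 1-D
interval-overlap matrices; each overlap fragment is weighted by
Δlat·Δlon·cos(mid-latitude). The operation is linear, conserves constants,
and masks destination cells with no unmasked source overlap.

## Spatiotemporal weight features

For a sample at (lat, lon, date) the spatial term is
`[Lat, Lon, sqrt(1/(D_i + δs)) for i = 1..9]` with D_i the Haversine
great-circle distances (sphere radius 6371.0088 km) to the four corners, four
edge midpoints and center of the configured study box; the temporal term is
`[DOY, 1/(D_j + δt) for j = 1..4]` with D_j the distance in days to the four
mid-season days of the same calendar year. Sixteen components in total.

Numerical choices:

- Inverse distances are undefined at an anchor, so offsets δs (km) and δt
  (days), both defaulting to 1, bound the features; a monotone offset does
  not materially change where tree models split.
- Day distances are cyclic, `min(|ΔDOY|, Y − |ΔDOY|)`, because seasonality
  wraps the year end; a linear mode is available by flag.
- Anchors derive from the configured bounding box, not the data extent, so
  the features are stable across runs and subsets.
- Mid-season anchor days are re-derived per calendar year, so leap years
  shift the anchors correctly.

## Gap filling: iterative extra-trees imputation

The imputer follows the missForest scheme with extremely randomized trees:
initialise missing entries with the column mean; order targets by ascending
missingness; per iteration, fit an extra-trees regressor per target on its
observed rows (all other columns, at their current imputed state, as
predictors) and overwrite the target's missing rows with the prediction. The
change statistic Δ = Σ(x_new − x_old)²/Σx_new² over imputed entries is
recorded per iteration. Two iterations are the default; an optional
stop-on-divergence mode returns the previous state when Δ rises. Observed
entries are preserved bit-exactly, a complete table is returned unchanged,
and out-of-bag R² per target is reported as a skill estimate.

For grid stacks, each product (ordered coarse → fine) is flattened to
(cell, day) rows and imputed with the complete covariates, the 16 ST
features, and every previously completed (regridded) coarser product as
predictors; the sample unit is the row, so a partially cloudy day contributes
both training and prediction rows.

Forest defaults: 100 trees, minimum leaf 5, `max_features = 1/3`, bootstrap
row subsampling at 50%. The feature and row subsampling are deliberate: at
the package's reference problem size (10⁴ cells × 30 days, half observed) a
full-feature fit costs minutes per iteration on one CPU for no measurable
skill gain on smooth geophysical fields, while the subsampled fit costs tens
of seconds. All knobs are exposed.

## Surface estimation: cascade forest

Layer *l* is trained on the original features concatenated with layer
*l−1*'s augmentation. During training the augmentation consists of per-forest
out-of-fold predictions (k = 3 folds within the training set), so no forest
ever predicts its own training rows — the standard guard against label
leakage between layers; at predict time the retained full forests provide the
augmentation. Each layer holds 2 random forests and 2 extra-trees forests
(100 trees, `max_features = "sqrt"`, min leaf 5) by default; layers are added
up to 10 while the k-fold layer RMSE improves (patience 1) and the cascade is
truncated at the best layer, which makes the retained layer-RMSE sequence
non-increasing by construction. Predictions are means over the final layer's
forests and therefore lie inside the training target range. No multi-grained
scanning stage is used: the inputs are tabular feature rows, not image
windows.

Seeding: the forest in slot *f* of layer *l* is seeded from
`SeedSequence((random_state, l, f))` and the layer's fold split from
`SeedSequence((random_state, l, 10000))`, making fits bit-reproducible and a
one-layer/one-forest cascade exactly equal to the corresponding standalone
forest.

Feature importances aggregate impurity importances over every forest of every
retained layer, attributed to the *original* features only: an augmented
feature's importance is redistributed proportionally onto its source forest's
own (already resolved) original-feature importances. Scores are non-negative
and normalised to 1.

A per-year flag (default on) trains an independent cascade per calendar year
when the sample dates span several years, since the column–surface
relationship drifts with emissions and retrieval versions.

## Validation

`make_folds` builds exact partitions: random-record folds from a shuffled
permutation, grouped ("out-of-city") folds by shuffling the distinct city
labels and assigning them round-robin, so no city is ever split. Held-out
predictions are pooled over folds before metrics are computed (per-fold
metrics are also returned); pooled metrics therefore depend only on the
partition, not on fold labels.

Metrics: RMSE, MAE, CV-R² as the squared Pearson correlation (the convention
of this literature; the Nash–Sutcliffe form 1 − SSE/SST is reported
alongside), and OLS slope/intercept of predicted on observed, so slope < 1
reads as low-biased predictions. Zero observed variance flags the
correlation-based metrics undefined rather than raising mid-pipeline.

## Synthetic scenes

The generator emulates the *structure* of the real inputs, not their physics:

- **Truth**: `exp(log-mean + smooth background + daily weather) + Gaussian
  urban hotspots`, modulated by a seasonal factor
  `1 + A·cos(2π(DOY − winter peak)/Y)` and floored at 0.5 μg/m³. Smooth
  fields are Gaussian random fields made by Gaussian spectral filtering of
  white noise (correlation length as the low-pass scale), standardised.
- **Column**: `scale · truth + static smooth distortion + white noise`,
  floored positive; a fine version is cloud-masked, a coarse version is
  aggregated, perturbed and left near-complete (87% coverage), mirroring the
  relative completeness of coarse vs fine instruments.
- **Cloud masks**: a per-day smooth field is rank-thresholded to retain
  exactly `round(coverage · n_cells)` cells — the target coverage is met
  exactly (default 51%) and the gaps are spatially clustered like real cloud
  fields. Rank selection rather than value thresholding keeps the count exact
  even when the field degenerates to near-constant ties on tiny grids.
- **Covariates**: a smoothed-and-perturbed model surface field, two daily
  meteorology-like fields that genuinely co-drive the truth's daily
  variability, a hotspot-derived population proxy, and two independent static
  fields (NDVI-like, elevation-like) that carry no causal signal.
- **Stations**: cells sampled with population-proxy-biased probability
  (emulating an urban-biased network), observations = truth + Gaussian noise
  with sd = 10% of the truth field sd by default, city labels from the
  nearest hotspot.

Default scene: 1°×1° at 0.01° (100×100 cells), 30 days from 1 January 2019,
200 stations, 10 hotspots, 51% fine coverage. Everything derives from one
seed; two scenes with the same config are bit-identical.

What passing tests on these scenes do **not** show: real retrieval biases are
not independent noise, cloud occurrence correlates with chemistry and season,
station QC pathologies are richer than the stuck-value rule, and the true
column–surface relationship involves boundary-layer physics absent here.
Synthetic skill numbers are therefore upper bounds on structure recovery, not
forecasts of real-data accuracy.

## Reference problem sizes

The package's own end-to-end checks use: gap filling on the default
100×100×30 scene; a recovery pipeline on a 50×50-cell, 120-day, 200-station
scene with a reduced cascade (1 RF + 1 extra-trees, 30 trees, ≤ 2 layers) for
both CV schemes; and a spatial-ablation study on a heterogeneity-dominated
scene (strong smooth background, weak hotspots, heavily degraded column and
model covariates, 150 stations, 18 cities) with five paired-seed replicates,
where removing the 16 ST features consistently worsens out-of-city RMSE.
These sizes were chosen as the smallest at which the studied effects are
unambiguous on a single CPU.

## Known limitations

- Longitude wrap-around (anti-meridian domains) is not handled; domains are
  regional boxes in [−180, 180).
- The imputer's `transform` refits on the new table (iterative imputation is
  inherently fit-time work); it is not a frozen-model transform.
- No uncertainty quantification on predictions.
- GeoTIFF output is not provided; NetCDF (scipy backend, classic format) and
  CSV are the interchange formats.
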