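# Methods

## The problem

Epidemiological studies of fine particulate matter (PM2.5) need daily
exposure estimates everywhere people live, but regulatory monitor
networks are sparse and city-biased, and many stations measure only
PM10. Satellite aerosol optical depth (AOD) offers km-scale coverage
but is column-integrated, cloud-masked on most days, and only weakly
related to surface concentrations on its own. `pmgrid` implements a
four-stage random-forest framework that fuses these sources into a
complete daily PM2.5 surface on a 1 km grid:

1. **Stage 1 — monitor augmentation.** A per-year forest learns
   PM2.5 from co-located PM10 plus monitor type, month, day-of-week
   and coordinates, then predicts PM2.5 on monitor-days where only
   PM10 exists. Reference hyperparameters: 500 trees, mtry 4.
2. **Stage 2 — AOD gap filling.** Per year and per wavelength
   (0.47 and 0.55 µm), a forest learns the QA-filtered daily satellite
   AOD composite from 35 modelled-AOD reanalysis columns (5
   wavelengths × 7 sub-day hours, nearest-centroid linked from the
   coarse grid) plus day-of-year and coordinates, then imputes every
   cloud-masked cell. Reference hyperparameters: 50 trees, mtry 20.
3. **Stage 3 — the exposure model.** A per-year forest for
   log PM2.5 at monitor cells from 15 spatio-temporal predictors
   (log model-surface PM2.5, the two imputed AOD bands, seven
   meteorological variables, boundary-layer height at 0:00 and 12:00,
   monthly NDVI, day-of-year, month, day-of-week) and 27 spatial
   predictors (four IDW-lagged annual PM2.5 averages entered as logs,
   two nearest-class monitor distances, elevation, nine land-cover
   shares, impervious fraction, night-time light, three road densities
   and three road inverse distances, population density, airport and
   seashore inverse distances). Targets are the Stage-1-augmented
   series; predictions are exponentiated (no smearing correction).
   Reference hyperparameters: 500 trees, mtry 20.
4. **Stage 4 — reconstruction.** The Stage-3 forests are applied to
   every grid cell and day (lagged features switch to the all-donors
   grid variant) and aggregated to period means.

All learners are scikit-learn `RandomForestRegressor` ensembles with
bootstrap bagging and out-of-bag (OOB) predictions. Low-cardinality
categorical predictors (monitor type, month, day-of-week) enter as
integer codes, the standard tree-ensemble equivalent of factor
predictors.

## Preprocessing rules

- Monitors from different networks whose series correlate to exactly 1
  (within 1e-9) on overlapping days and sit < 0.1 km apart are
  duplicates; the preferred network's station is kept. (The source
  rule gives no numeric thresholds; these operationalize "the same
  temporal distribution at approximately the same coordinates".)
- A monitor-day needs ≥ 18 hourly values per pollutant; after that a
  monitor-year needs ≥ 30 surviving days per pollutant. The hour rule
  is applied to PM10 symmetrically with PM2.5 — a documented choice,
  not an attested one.
- AOD overpass values require the best-quality QA flag and retrieval
  uncertainty ≤ 0.05 (configurable); survivors are averaged per day.
- Coarse fields map to the km grid by nearest pixel centroid, ties to
  the lowest pixel index. Cell membership of points is half-open
  ([left, right) × [bottom, top)).

## Spatially-lagged features

For each target and year, the annual mean PM2.5 of every *other*
monitor of a class (background = urban/suburban/rural, hotspot =
traffic/industrial) is combined with normalized inverse-distance
weights: power 1 ("regional") and power 2 ("local"). Distances are
Euclidean km, floored at 0.5 km (half a cell) so co-located pairs
cannot generate infinite weights. Annual means use observed PM2.5
only, not Stage-1 predictions (a config switch enables the augmented
variant). During k-fold CV the lagged features are, by default, not
recomputed per fold; `strict_cv` enables the leakage-controlled
variant in which held-out monitors are removed from the donor pool of
every fold's features. A caveat discovered while testing: the
intuition "the power-2 estimate is always closer to the nearest
donor's mean than the power-1 estimate" is provable only for two
donors; with three or more donors counterexamples exist, so only
convexity (the estimate lies within the donor mean range) is a true
invariant.

## Validation

Predicted values are regressed on observed values by OLS; reported
statistics are R² (squared Pearson correlation, direction-invariant),
RMSE of raw errors (not regression residuals), intercept and slope.
Besides OOB statistics, a 10-fold cross-validation over *monitors*
(uniform random groups) measures skill at unseen locations. Overall
statistics use the pooled series; the spatial component regresses
per-monitor means (n = monitors, allowed down to 2); the temporal
component uses pooled per-monitor-centered deviations — both centered
series average to exactly zero, so the temporal intercept is
structurally 0 for any input, a useful integrity check. Seasonal
stratification uses meteorological seasons (DJF/MAM/JJA/SON).
Predictor importances are impurity-based split-gain importances
normalized to percentages.

## The synthetic study region

The generator produces a planar km grid (coordinates are covariates,
no map projection) with latent

    log PM2.5(s,t) = µ + regional(s) + hotspot(s) + season(t)
                     + weather(s,t) + ε(s,t)

- µ = log 9 µg/m³; `regional` is three broad Gaussian bumps
  (amplitudes ±0.25–0.30); `hotspot` is sparse narrow bumps (width
  1–1.8 km, amplitude 0.3–0.6) co-located with high road density,
  imperviousness and population; `season` is an annual cosine of
  amplitude 0.22 peaking in early January; `weather` is linear in
  standardized log boundary-layer height (−0.30), wind speed (−0.15),
  temperature (+0.05) and capped precipitation (−0.12); ε is i.i.d.
  Gaussian with scale `sigma_resid` = 0.20.
- PM10 = PM2.5 / r with r ~ N(0.6, 0.07) truncated to (0.3, 0.95);
  monitor observations carry 2% multiplicative noise. Hourly counts
  come from a mixture (87% full days, some partial, some failing, and
  occasional sparse monitor-years) so the completeness filters bind.
- Column AOD at 0.55 µm is 0.02 · exp(smooth log PM2.5) · BLH/1000 —
  the *residual-free* component, since column AOD reflects the
  regional aerosol burden, not cell-day surface noise — scaled to the
  other wavelengths by a fixed Ångström-type factor (λ/0.55)^−1.3.
  Two daily overpasses add N(0, 0.015) retrieval noise, share a
  spatially correlated cloud field whose per-day masked fraction is
  the seasonally modulated target (default 90%, more missing in
  winter), and carry best-quality QA flags with probability 0.95.
- The modelled-AOD reanalysis is the block mean of true AOD on a 10×
  coarser grid, scaled by a smooth diurnal profile over seven sub-day
  hours, plus a static smooth bias per wavelength. The model PM2.5
  surface is the truth smoothed over 5×5 cells times a static
  lognormal (σ = 0.25) spatial bias. Meteorology combines national
  seasonal/AR(1) daily series with smooth static anomalies and an
  AR(1)-weighted spatial pattern per variable.
- Noise defaults were calibrated once so the synthetic world sits in
  the reported performance regime (Stage-1 OOB R² ≈ 0.93, Stage-2 OOB
  R² ≈ 0.92–0.94, Stage-3 10-fold overall R² ≈ 0.76–0.78) and satisfies
  the generator invariants (satellite AOD vs truth × mixing-depth
  correlation > 0.7; realized missingness within 2 points of target).

What the generator does *not* emulate: real retrieval physics
(radiative transfer, surface brightness), true emission inventories,
hourly concentrations (completeness is metadata only), terrain-driven
meteorology, or population dynamics. Passing recovery tests therefore
demonstrates that the pipeline's statistical machinery is correct and
unbiased under its own assumptions — not that the real-data accuracy
figures would be reproduced on new archives.

## Numerical and design choices

- Back-transform of Stage-3 output is plain exponentiation; a
  smearing-type correction is available behind config but off by
  default, since the reference procedure applies none.
- Wind direction enters as raw degrees (one column, preserving the
  15-predictor count); a circular encoding is a config option.
- The boundary-layer pair is 0:00 and 12:00.
- "Week" in the Stage-3 predictor list is read as day-of-week,
  consistent with Stage-1's predictor set.
- Missing predictor values at table-assembly time raise an error
  naming the column and key; nothing is imputed silently.
- Fold assignment is unstratified uniform random over monitors;
  stratification by class is a config option.
- Stage-3 rows with Stage-1-predicted targets are weighted equally
  with observed rows.
- Gridded output is CF-style NetCDF (scipy backend, doubles for the
  world files so round-trips hold to 1e-6; float32 for reconstruction
  products) or single/multi-band TIFF with pixel-scale/tiepoint
  georeferencing tags.

## Problem sizes and runtime defaults

The bundled desk-scale configuration uses a 40×40 km grid, 120
monitors, one year, 100-tree forests for Stages 1 and 3 (50 for
Stage 2, as in the reference setting), 10-fold CV, and a 30-day
stride for the Stage-4 demonstration grid; a full run takes a few
minutes on one core. Unit tests run 16×16 and 8×8 worlds with smaller
forests. The reference 500-tree settings and national-scale grids are
reached by configuration (`LearnerSpec`, `WorldConfig`), not code
changes.

## Known limitations

- The duplicate-monitor scan is O(n²) over sites with pairwise series
  correlation; fine for hundreds of monitors, not for tens of
  thousands.
- Stage-2 trains on composited daily values; per-overpass modelling
  is not implemented.
- OOB statistics at very small tree counts can include rows that were
  never out-of-bag (scikit-learn returns 0 for those); use ≥ 50 trees
  for meaningful OOB numbers.
- The temporal decomposition assumes each monitor's mean is estimated
  from its own series; monitors with a single day contribute zero
  deviations.
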