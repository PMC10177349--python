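# Methods

## The question and the measurement

Grazing livestock distribute themselves over a paddock in response to
forage, terrain, infrastructure and weather. `grazedrivers` quantifies that
response from GPS collar data in four stages:

1. **Fix cleaning.** A collar records bursts of fixes (default at 0, 15, 30,
   45 and 60 s within a minute, then 4 min of sleep — 60 fixes per animal per
   hour). Fixes whose time-to-fix exceeds 16 s are positionally unreliable and
   are removed; the rule is strict (a fix of exactly 16 s is kept). Fixes
   outside the paddock polygon are removed, but fixes exactly on the ring are
   kept — fence-line residency is a real behaviour, not an artefact. Duplicate
   (animal, timestamp) records keep their first occurrence. Cleaning is
   idempotent and fully accounted: retained + removed-per-rule = input.

2. **Residency index.** The paddock is tiled with 5 × 5 m half-open cells
   (origin snapped down to a cell multiple so nested resolutions align). The
   livestock residency index (LRI) of a cell in an hour is the number of
   retained fixes falling in it divided by all fixes recorded at that level
   (animal or pooled treatment) in that hour, so hourly LRI sums to one over
   cells and is comparable across hours with different dropout. Raw counts
   are kept alongside; hours with no fixes are undefined, never zero-filled.
   The per-fix model target is the *treatment-level* LRI of the fix's
   cell-hour, giving one model row per retained fix.

3. **Covariates.** Twelve predictors per row: animal identity (integer-coded
   categorical), easting/northing, near distances to trees, water troughs and
   fence lines (point-to-point / point-to-segment minima; the boundary edges
   serve as fences when no separate layer exists), NDVI and elevation sampled
   at the containing raster cell, terrain aspect (Horn 3 × 3 finite
   differences on a replicated-edge DEM, downslope azimuth with 0° = north,
   clockwise; cells with gradient below 10⁻⁶ are flat and their rows are
   dropped), and hourly temperature, rainfall and a sheep chill index joined
   by flooring the fix time to the hour. NDVI surfaces can be interpolated
   from transect samples by inverse-distance weighting (power 2, all
   samples; exact at coincident cell centres) — a deterministic,
   oracle-checkable stand-in for geostatistical interpolation, adequate for a
   5 m proxy surface. A variance-inflation-factor screen (VIF = 1/(1 − R²)
   from an OLS regression of each column on the rest; iteratively drop the
   worst while it exceeds 5, ties broken by name) is available for wider
   weather tables.

   The chill index is `C = (11.7 + 3.1 v^0.5)(40 − T) + 481 + 418(1 −
   e^(−0.04 R))` kJ m⁻² h⁻¹ (T °C, v m/s, R mm/h): convective loss down the
   body-to-air gradient, basal radiative loss, and a saturating wet-fleece
   evaporative term. The formula is pluggable; published sheep chill
   formulations differ in coefficients.

4. **Driver models.** A regression forest (default 500 trees, mtry = 4 =
   ⌊12/3⌋, leaf size 5) predicts the LRI target. Models are fit per trial,
   treatment, and hours mode — all hours (AH) or grazing hours only (GH,
   rows restricted to intervals when grazing was observed) — sixteen models
   for a four-trial, two-paddock study.

## Validation design: why two R² values

Burst sampling makes fix-level rows *near-duplicates*: the five fixes of a
burst usually land in one 5 m cell and share the target exactly, and
landscape covariates sampled on the grid are identical within a cell. Two
consequences, both deliberate:

- **Bagging OOB R²/MSE** (`oob_r2_`, `oob_mse_`) use the classical per-row
  bootstrap. They are comparable with standard forest reports but are
  optimistic on collar data: an out-of-bag row is predicted from its in-bag
  near-duplicates, so even a no-driver simulation scores OOB R² ≈ 0.8–0.9.
  This is the spatial-autocorrelation optimism long noted for such data, and
  reproducing it (rather than hiding it) is informative.
- **Blocked validation** (`val_r2_`, `val_mse_`, `importances_`) holds out
  *whole hours*. The estimator partitions hours into three folds, fits a
  forest per fold-complement, scores permutation importance (mean MSE
  increase, 2 repeats) on each held-out fold and averages; pooled
  out-of-fold predictions give the validation R². Held-out hours share no
  burst with training, so this measures generalisation. Under a no-driver
  simulation it sits at chance (≈ 0); under a real driver it is ≈ 0.3–0.9
  depending on flock cohesion. Fold averaging exists because a single
  held-out block can be unrepresentative (e.g. the only rainy hours),
  which otherwise scrambles the importance ranking on a few percent of
  seeds.

`n_calibration_`/`n_validation_` report the first fold's ≈ 2:1 split, the
partition shape conventional for these models.

## Importance significance

P-values come from target permutation (Altmann-style): permute the target B
times (default 100, the minimum that can resolve p ≤ 0.01 as
p = (1 + #{null ≥ observed})/(1 + B)), refit and rescore importance each
time. Full-size refits at B = 100 are prohibitively slow, so the procedure
runs at a reduced, *shared* configuration — 25-tree forests on a subsample
of at most 2000 rows (1600 in the recovery harness) — for both the observed
statistic and the nulls, keeping the
comparison on one scale. The observed statistic is averaged over five
calibration/validation splits; null draws use one split each, so the null
distribution also carries split variability and the test is mildly
conservative. On the synthetic study conditions this detects a dominant
driver at p ≤ 0.01 while flagging zero-weight drivers at well under the
nominal 1% rate.

Partial dependence is the set-and-average definition: for each grid value g
over a predictor's observed range (its levels, for the categorical animal
code), set the column to g for every row and average the forest predictions.

## The simulator

Synthetic trials are the package's ground truth, emulating a two-paddock
sheep study design: ~22.5 ha rectangular paddock, 15 collared animals,
six-day trials (shorter for fast checks), trees scattered or clustered in
the northern end, a water trough in the south-west corner, a north-rising
elevation surface spanning 930–985 m with smooth relief, a smooth NDVI
surface in [0.1, 0.4], and hourly weather (sinusoidal diurnal temperature
peaking at 14:00, sparse exponential rain events, AR(1) wind).

Animals move as a minute-resolution biased correlated random walk. The bias
is the gradient of a utility surface — a weighted sum of standardised
covariate fields (NDVI, elevation, negative tree distance, negative trough
distance, plus a tree-shelter term that switches on when the chill index
crosses a threshold) — and the weights are the ground truth the analysis
must recover. The gradient keeps its magnitude, scaled by the field
correlation length (gain 0.25 × smoothness × cell size), so weights set the
*strength* of attraction: a weight of ~2 makes the attraction term
comparable to the heading-persistence term and is what the scenario library
uses for a "dominant" driver. Headings mix persistence (0.6), bias,
mild attraction to the flock centroid (0.15) and circular noise (0.6).
Step length is the state speed (resting 0.01, grazing 0.08, travelling
0.30 m/s) times 60 s; activity states follow a dawn/dusk-peaked diurnal
schedule with 0.85 per-minute persistence; the boundary reflects, so
positions never leave the paddock and fence-adjacent residency arises
naturally.

The observation model samples the collar duty cycle from the minute
trajectory (linear interpolation within the minute), adds Gaussian jitter
(0.8 m), draws time-to-fix with P(ttf > 16 s) = 0.05, and drops 2% of fixes
— so cleaning has real work and its bookkeeping can be audited against
planted counts.

What the simulator does **not** emulate: GPS error autocorrelation and
multipath near trees, individual personalities, rumination/energetics,
pasture depletion feedback, and measurement noise on the covariate layers
(the simulated landscape layers are noiseless functions of position).
Passing recovery tests therefore show the chain is correct and powered for
this class of data-generating process, not that field inference is immune
to covariate measurement error.

Scenario library: `ip-like` (dominant NDVI weight 2.0 — greenness-driven,
improved-pasture style), `np-like` (elevation 1.2 + tree shelter 1.0,
clustered northern trees — native-pasture style), `null` (all weights and
cohesion zero), `weather-driven` (shelter weight 2.0 activated above a
chill threshold). All randomness derives from a single seed through named
sub-streams; identical configs give byte-identical trajectories, fixes and
model tables.

## Validation harness and problem sizes

`grazedrivers.validation` runs the recovery studies end to end: one
simulated day of 15 animals (~21.6 k scheduled fixes, ~18.8 k retained),
forests of 100 trees fit on a subsample of at most 8000 rows, significance
at B = 100 on 1600-row subsamples. With 20 seeded replicates per scenario
this completes in minutes on one core while leaving the checks comfortably
powered: the dominant driver is recovered (rank ≤ 3 and p ≤ 0.01) in
≥ 90% of runs for both driver scenarios, zero-weight drivers are flagged in
0–5% of null runs, and the null blocked-validation R² without coordinates
stays at chance.

One measured caveat worth restating: because the simulated covariates
pinpoint position exactly, adding easting/northing to the full 12-predictor
model does not raise bagging OOB R² (it dilutes mtry slightly); the
coordinate-memorisation inflation is demonstrated against the non-spatial
predictor set {A, T, R, WC}, where adding EA/NO lifts OOB R² dramatically
for every seed.

## Numerical conventions

- Grid cells and hour bins are half-open; points on the extent's maximum
  edge belong to the last cell, a fix at exactly the hour boundary to the
  later hour.
- Importance ranks are 1 = largest score; exact ties break by predictor
  name so reports are deterministic.
- IDW weights are d⁻²; a cell centre within 10⁻⁹ m of a sample takes the
  sample value (no 0/0).
- All timestamps are timezone-aware; trial windows are declared explicitly
  (field trials can straddle daylight-saving changes).
- Degenerate inputs fail loudly (constant targets, empty feature sets,
  polygons without area, weather gaps), with one exception: cleaning that
  removes every fix returns an empty trajectory and a warning, because a
  collar that failed for one animal should not abort a flock-level analysis.
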