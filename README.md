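# grazedrivers

**What drives where grazing livestock spend their time?**

`grazedrivers` turns raw GPS-collar fixes from flocks on fenced paddocks
into an answer: it cleans the fixes, grids them into a **livestock residency
index** (LRI), assembles a twelve-predictor landscape/weather covariate
table, and fits random-forest models whose permutation variable importance —
with significance from target-permutation nulls — ranks the drivers of
residency. Because collar datasets of this kind are rarely public, the
package ships a flock simulator with *known* driver weights, so the whole
chain is validated by parameter recovery.

It is written for movement ecologists and livestock scientists analysing
collar trials (sheep, cattle, goats) on bounded paddocks, and for anyone who
needs a reproducible, oracle-tested residency pipeline.

## The model

For animal fixes cleaned of slow (> 16 s time-to-fix) and out-of-boundary
records, the residency index of 5 × 5 m cell *c* in hour *h* is

    LRI(c, h) = n(c, h) / Σ_c' n(c', h)

where *n* counts the pooled fixes of a treatment's collared animals. Each
retained fix becomes one model row

    LRI ~ f(A, EA, NO, NT, NW, NF, NDVI, AS, EL, T, R, WC)

with *f* a regression forest (500 trees, mtry = 4, out-of-bag R²/MSE):
animal identity, coordinates, near distances to trees / water troughs /
fences, vegetation greenness, terrain aspect and elevation, and hourly
temperature, rainfall and sheep chill index
C = (11.7 + 3.1 v^0.5)(40 − T) + 481 + 418(1 − e^(−0.04R)).
Importance is permutation importance scored on held-out hours (fix bursts
duplicate the target within a cell-hour, so row-level evaluation leaks);
significance uses Altmann-style target-permutation nulls at α = 0.01;
partial-dependence curves show each driver's marginal effect. Models are fit
per trial × treatment for all hours (AH) and grazing-observed hours (GH).

## Worked example

Simulate an improved-pasture-style trial (greenness-driven, NDVI weight
dominant), run the full pipeline, and fit a driver model:

```python
from grazedrivers import get_scenario, run_pipeline, fit_rf

cfg = get_scenario("ip-like", seed=1, n_days=1, n_animals=15)
bundle = run_pipeline(cfg)

rep = bundle["clean_report"]
print(f"raw fixes: {rep.n_input}   retained: {rep.n_retained} "
      f"(slow fix: {rep.n_slow_fix}, outside: {rep.n_outside})")

est, res = fit_rf(bundle["table"], n_trees=200, seed=1)
print(f"OOB R2: {res.oob_r2:.3f}   OOB MSE: {res.oob_mse:.2e}   "
      f"held-out-hours R2: {res.val_r2:.3f}")
print(res.importance.head(4).to_string(index=False))
```

prints

```
raw fixes: 21172   retained: 20018 (slow fix: 1057, outside: 97)
OOB R2: 0.942   OOB MSE: 1.13e-05   held-out-hours R2: 0.151
predictor  importance  rank
     NDVI    0.000048     1
       EL    0.000012     2
       NF    0.000007     3
       NW    0.000006     4
```

Reading the numbers: of 21 172 raw fixes, the 16-second time-to-fix rule
removed 1057 and the boundary rule 97. The forest's bagging OOB R² (0.942)
is in the optimistic regime typical for autocorrelated collar data — bursts
of fixes share their cell-hour target — while the held-out-hours R² (0.151)
is the honest generalisation figure for this loosely cohesive simulated
flock. The importance ranking recovers the planted driver: NDVI, the
covariate the simulation actually used to bias movement, ranks first.

The same chain runs from the shell:

```sh
grazedrivers simulate --scenario np-like --seed 7 --out data/
grazedrivers fit --table data/model_table.csv --out report/
```

and `run_full_study` fits the sixteen-model family (4 trials × 2 paddocks ×
{AH, GH}) with a performance table and a 12 × 16 importance-ranking table.

## Layout

- `grazedrivers.trajectory` — fix reading, cleaning rules, hour indexing
- `grazedrivers.movement` — step distances/speeds, behaviour recoding,
  hourly activity summaries
- `grazedrivers.residency` — 5 m grid, LRI, per-fix target lookup, export
- `grazedrivers.covariates` — near distances, aspect, IDW NDVI, wind chill,
  weather join, VIF screen, model-table assembly
- `grazedrivers.model` — `ResidencyDriverForest` (scikit-learn estimator),
  importance p-values, partial dependence, the 16-model study runner
- `grazedrivers.simulate` — landscape/weather generators, biased correlated
  random walk, collar observation model, scenario library
- `grazedrivers.validation` — parameter-recovery harness
- `docs/methods.md` — modelling assumptions, parameter defaults, and the
  simulator's scope and limits
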