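# coashift

Tools for asking whether social migration behaviour predicts how fast
North American migratory birds shift their seasonal ranges. Birds that
migrate in mixed-age flocks give naïve juveniles the chance to learn
novel routes from experienced adults; if social transmission matters
for range dynamics, such species should show faster long-term shifts in
their seasonal centres of abundance than species whose juveniles
migrate alone or in separate cohorts. `coashift` implements the full
analysis chain needed to test that prediction from survey, banding and
trait data — and, because the original survey posteriors are not
redistributable, ships a synthetic-data generator that reproduces the
statistical structure of every input with known ground truth.

The package is aimed at movement ecologists and comparative biologists
who work with stratum-level abundance indices (Breeding Bird Survey /
Christmas Bird Count style), bird-banding records, and phylogenetic
regression.

## The statistics

**Centre of abundance (COA).** For one species, season and year, with
stratum abundance indices `I_s` at centroids `x_s` (latitude or
longitude, in degrees):

    COA = Σ_s I_s x_s / Σ_s I_s

Posterior SDs of the indices are recovered from their 95% bounds,
`sd = (hi95 − lo95) / 3.92`, and pushed through the ratio by the
first-order Taylor (delta) method. Per-axis trends over 1970–2019 are
OLS slopes (linear in the annual COAs, so their variance propagates
exactly), and the two axes combine into a single displacement

    d = √(a² + b²)   [metres/year],   Var(d) = (a²Var(a) + b²Var(b)) / d²

after converting degrees to metres (111,320 m/deg; longitude scaled by
cos of the species' mean COA latitude).

**Cohort timing.** Latitude of banding events is smoothed on Julian day
with a 10-basis-function penalized cubic regression spline (smoothing
parameter by generalized cross-validation), separately for hatch-year
and after-hatch-year birds, inside the autumn window where the pooled
curve declines. Both curves are min–max normalised and compared by the
proportional overlap in area under the curve, `∫min / ∫max`; an index
strictly above 0.85 classifies the species as a mixed-age migrant.

**Trait inference.** Per-species displacement (± SE) is regressed on
traits by phylogenetic generalized least squares with residual
covariance `V = σ²C + diag(se²)`, where `C` is the Brownian-motion
correlation implied by the tree and `se` the propagated shift SEs
(reciprocal-SE weighting). σ² is profiled by REML for inference and by
ML when candidates are compared. The global model is screened at
VIF > 5, all nested submodels are ranked by AICc (submodels with fewer
than 10 species per predictor are dropped), and candidates within 2
AICc units of the best are averaged with Akaike weights; a term is
significant when its 95% CI excludes zero.

## Worked example

```python
import coashift as cs

scen = cs.SimScenario(n_species=81, velocity_north=3000.0, seed=42)

# 1. a species drifting north at a planted 3,000 m/yr
idx = cs.simulate_index_series(scen, "sp001")
print(cs.COAShiftModel(idx).fit().summary())

# 2. cohort timing from banding records with a 40-day age separation
band = cs.simulate_banding(scen, "sp001", cohort_separation=40.0)
print(cs.CohortTimingModel(band).fit().summary())

# 3. trait inference on an 81-species pool with planted class effects
tree = cs.simulate_tree(81, seed=42)
traits, truth = cs.simulate_traits(tree, scen, seed=42)
traits, _ = cs.zscore_columns(traits, list(cs.traits.NUMERIC_PREDICTORS))
corr = cs.brownian_correlation(tree, order=traits["species"].tolist())
print(cs.fit_trait_models(traits, corr, variant="B").summary())
```

prints

```
COA shift: sp001 (nonbreeding)
  years used          50
  trend latitude      +0.026503 ± 0.000799 deg/yr
  trend longitude     +0.000101 ± 0.000963 deg/yr
  displacement        2950.3 ± 88.9 m/yr

Cohort timing: sp001
  records (HY/AHY)   1514/1486
  autumn window      days 190-326
  overlap index      0.609
  classification     age_separated

Model averaging: 12 of 503 candidates within window (full averaging)
  VIF-removed predictors: total_range_km2
  term                                coef         se                    95% CI  sig
  Intercept                      -115.1941   446.5529    [  -990.42,    760.03]
  habitat_specialism             -137.7394   164.2213    [  -459.61,    184.13]
  flocking_behaviour[age_separated_flocks]   1029.2354   268.7400    [   502.51,   1555.96]  *
  flocking_behaviour[mixed_age_flocks]   2840.5611   326.9759    [  2199.70,   3481.42]  *
  ...
```

The COA stage recovers the planted 3,000 m/yr drift as 2,950 ± 89 m/yr
(the planted survey noise explains the gap); the 40-day cohort
separation yields an overlap of 0.61, well under the 0.85 threshold;
and the model-averaged mixed-age coefficient (2,841 ± 327 m/yr, CI
excluding zero) recovers the scenario's planted 2,660 m/yr mixed-age
effect over solo migrants.

The same chain is scriptable end to end:

```sh
coashift run-all --seed 4 --outdir results/
```

simulates a study, estimates every species' COA shift, classifies
cohort timing, assembles the analysis tables and fits/averages the
four trait models (2 seasons × model variants A and B), leaving a run
manifest for provenance.

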