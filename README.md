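# qgmix

Quantile g-computation for air-pollutant mixtures, with geospatial
exposure construction and a calibrated synthetic-cohort simulator.

## The problem

Epidemiologic studies increasingly ask what a *mixture* of correlated air
pollutants does to health, rather than one pollutant at a time.  The
motivating analysis for this package examined self-reported autoimmune
skin disease (psoriasis or eczema) in a cohort of 9,060 adults, combining
seven PM2.5 compositional species (NH4, black carbon, nitrate, organic
matter, sulfate, sea salt, soil), five criteria pollutants (CO, NO2, O3,
PM10, SO2), four volatile organics accumulated from industrial point
sources (benzene, ethylbenzene, toluene, xylene), and road density within
5 km — 17 exposures in all — while adjusting for age, sex, smoking
history, family history of rheumatoid arthritis, and other autoimmune
disease.

`qgmix` implements that full analysis chain as a reusable, tested
library:

1. **Exposure construction** — nearest population-weighted centroid
   linkage, raster cell extraction, 2000–2015 multi-year averaging,
   exponentially decayed point-source burdens
   `X_i = Σ_j C_0j · exp(−3 d_ij / a_r)` truncated at a 5 km buffer, and
   road length clipped to a 5 km disc.
2. **Quantile g-computation** — each exposure is coded into octiles
   (`q = 8`); a joint logistic model
   `logit P(Y=1 | X^q, Z) = β₀ + Σ_j β_j X^q_ij + Σ_k α_k Z_ik`
   is fit by hand-written IRLS; the conditional mixture effect is
   `ψ = Σ_j β_j` (log odds ratio per one-octile increase in *every*
   exposure simultaneously); signed weights
   `w_j = β_j / Σ(same-sign β)` partition into +1 / −1; a g-computation
   marginal structural model refits the counterfactual outcome
   probabilities at each octile level; inference comes from a
   nonparametric bootstrap (breakpoints re-estimated per resample).
3. **Synthetic cohorts and landscapes** — demographic marginals, exposure
   means/SDs/correlations, and effect sizes are calibrated to the
   published study's printed tables, so planted-truth recovery
   experiments run without any restricted data.

Users are expected to work mainly from Python (`import qgmix`); a thin
`qgmix` CLI (`simulate`, `link`, `fit`, `run`, `sensitivity`) wraps the
same functions for shell pipelines.

## Worked example

```python
from qgmix.pipeline import RunConfig, covariates_for_fit, simulate_cohort
from qgmix.qgcomp import fit_qgcomp

cfg = RunConfig(seed=7, preset="per_component", bootstrap=0, exposure_mode="direct")
cohort, exposures, coeffs = simulate_cohort(cfg)   # planted published truth
z = covariates_for_fit(cohort)
result = fit_qgcomp(exposures, z, cohort["outcome"].to_numpy(), q=8, b=200, seed=7)
print(result.table[["or", "ci_low", "ci_high", "p", "weight"]].round(4))
```

prints (abridged; full script in `examples/03_fit_mixture.py`):

```
                     or  ci_low  ci_high       p  weight
psi_conditional  1.0889  1.0386   1.1556  0.0018     NaN
psi_marginal     1.0878  1.0380   1.1538  0.0018     NaN
so4              1.0462  1.0144   1.0887  0.0216  0.1961
...
smoked_100       1.1324  0.9993   1.2863  0.0685     NaN
sex_male         0.8269  0.7192   0.9575  0.0093     NaN
```

The planted conditional mixture OR here is 1.1123; the estimate 1.0889
(95% bootstrap CI 1.039–1.156) recovers it within sampling error: raising
every exposure by one octile raises the odds of the outcome by ~9% in
this replicate.  `psi_marginal` is the population-averaged analogue from
the g-computation marginal structural model (slightly smaller, as
expected under a non-collapsible logistic link).  The `weight` column
gives each component's share of the same-sign mixture effect — sulfate
carries the largest positive share, matching the published pattern.

Each script in `examples/` demonstrates one capability: cohort
simulation, spatial linkage, mixture fitting, leave-one-out sensitivity,
and replicated parameter recovery.

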