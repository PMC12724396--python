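# hppeval

Do heat prevention plans (HPPs — heat-health warning systems and action
plans) actually reduce heat-related mortality? `hppeval` is a Python
implementation of the three-stage epidemiological design used to answer
that question from multi-city daily time series of mean temperature and
death counts, packaged for environmental epidemiologists and biostatistics
methodologists who want a tested, reproducible version of the full
pipeline with a synthetic ground truth to validate it against.

## The method

**Stage 1 — city × subperiod exposure–response curves.** In each city and
each 3-year subperiod, warm-season (May–September) daily deaths follow a
quasi-Poisson distributed-lag non-linear model (DLNM):

    log E[Y_t] = α + ns(dos_t, 4) × year + dow + cb(x_t, lag 0..10)

where `cb` is the cross-basis of a quadratic B-spline in temperature
(knots at the 50th/90th percentile of the city's full-period warm-season
distribution) with a natural cubic spline over 10 days of lag (2 knots,
log-spaced). The fit is reduced to the overall cumulative curve, giving
the relative risk RR(x) against the subperiod- and city-specific minimum
mortality temperature (MMT).

**Stage 2 — multilevel longitudinal meta-regression.** The reduced curve
coefficients θᵢⱼ (4-vectors with known covariance Sᵢⱼ) are pooled across
city i and subperiod j:

    θᵢⱼ = (xᵢⱼ ⊗ I₄) β + b0ᵢ + tᵢⱼ·b1ᵢ + εᵢⱼ

with an HPP presence indicator, Region × Time fixed effects (the main
"Model 3"; variants add HPP × Region or stratify the HPP effect by the
plan's tercile score class), city-level random intercepts and time slopes
with diagonal covariance, maximum-likelihood estimation, and likelihood
ratio tests of the HPP terms.

**Stage 3 — counterfactual attribution.** BLUP curves per city ×
subperiod are predicted under the factual scenario (HPP as observed) and
a counterfactual with the HPP indicator forced to zero. On days above the
95th warm-season temperature percentile, the attributable fraction
(RR−1)/RR converts deaths into heat-attributable numbers, fractions (HAF,
% of warm-season deaths) and rates (HAD, annual deaths per 100 000, 2015
populations). The protective effect of HPPs is the contrast
(HAF_fact − HAF_cf)/HAF_cf over post-implementation subperiods, with 95%
empirical CIs from 1000 Monte-Carlo draws of the meta-regression
coefficients.

A synthetic multi-city generator (`hppeval.synthetic`) produces cohorts
with this exact structure — overdispersed counts, lagged nonlinear heat
effects, region-specific risk trends, per-country HPP onset years — and
closed-form true HAF/HAD under both scenarios, so the whole pipeline can
be validated by parameter recovery.

## Worked example

A recovery experiment: 30 cities in 10 countries, daily series 1993–2016,
plans implemented in staggered years, each cutting the above-MMT log-risk
slope by 30% (`hpp_effect: 0.7`).

```yaml
# demo.yaml
truth:
  n_cities: 30
  n_countries: 10
  years: [1993, 2016]
  hpp_effect: 0.7
n_samples: 250
```

```sh
hppeval run-all --config demo.yaml --seed 1 --out results/demo
```

prints

```
overall HAF change -29.6% [-39.6, -16.6] (truth -27.0%); LRT p=3.77e-05
```

i.e. the pipeline estimates that HPPs reduced extreme-heat-attributable
deaths by 29.6% (95% CI 16.6–39.6%), covering the generator's true −27.0%,
and the likelihood-ratio test against the no-HPP meta-regression is
decisive. `results/demo/` contains the per-scope attribution table
(`attribution.csv`: HAF/HAD under both scenarios with CIs at location,
country, region, HPP-class and overall level), per-subperiod HAF
trajectories, the stage-1 fits (JSON lines), the stage-2 model and a run
manifest. The same stages are available individually (`hppeval simulate`,
`stage1`, `stage2`, `attribute`, `recovery-experiment`) and as library
functions (`hppeval.run_all`, `hppeval.fit_meta`, …).

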