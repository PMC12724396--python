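# Methods

`hppeval` implements a three-stage evaluation of heat prevention plans
(HPPs — heat-health warning systems and action plans) against daily
mortality, together with a synthetic data generator that provides known
ground truth for every statistical claim the pipeline makes.

## Stage 1 — location × subperiod quasi-Poisson DLNM

For each city and each 3-year subperiod (blocks aligned to 1990 + 3k),
daily warm-season (May–September) death counts are modelled as

    log E[Y_t] = α + s(dos_t, 4 df) × year_t + dow_t + cb(x_t, …, x_{t−10})

with a natural cubic spline in day of season (days since April 30,
interacted with a calendar-year indicator so each year gets its own
seasonal shape), day-of-week dummies (reference Monday), and a
distributed-lag non-linear cross-basis `cb`: quadratic B-spline in the
exposure (two internal knots) tensor-multiplied with a natural cubic lag
spline (intercept, two internal knots log-spaced over lags 0–10; knots at
10^(1/3) ≈ 2.15 and 10^(2/3) ≈ 4.64 days). Fitting is Poisson IRLS;
standard errors are inflated by the Pearson-χ² dispersion (quasi-Poisson).
The fitted cross-basis is collapsed over the lag dimension into the overall
cumulative exposure–response curve (4 coefficients + covariance), which is
recentred at the curve's own minimum-mortality temperature (MMT), found by
grid search over the 1st–99th exposure percentile.

**Percentile-scale exposure.** The exposure enters the cross-basis as the
day's *percentile* in the city's full-period May–September temperature
distribution, with spline knots at the 50th and 90th percentile and
boundaries at the observed range. On this scale the knots of every city
coincide, so the 4-vector curve coefficients of all cities live on a single
common basis and can be pooled directly in stage 2 — the standard device for
pooling exposure–response curves across heterogeneous climates. Each curve
carries its location's percentile → °C table, so MMTs and displayed curves
are reported in degrees. Fitting in percentile space rather than degrees
changes the spanned function family slightly (a monotone reparameterisation
of the axis), but makes cross-city pooling exact instead of an approximate
re-projection between per-city bases.

Out-of-boundary exposures (possible for lag look-back days outside the
warm season) are evaluated by clamping to the boundary knot — constant
extrapolation prevents wild quadratic behaviour at record values. Lag
windows of early-May days deliberately reach back into late April: the
cross-basis is built on the full daily series and only the *outcome* days
are restricted to May–September. Blocks with fewer than 270 analysed days
are dropped (configurable). A sensitivity switch removes June–August 2003
(the exceptional European heatwave) from stage-1 fitting; "summer" is read
as JJA there, with the month set configurable.

## Stage 2 — multilevel longitudinal multivariate meta-regression

Units are city × subperiod curves θ_ij (4-vectors with known within-unit
covariance S_ij from stage 1):

    θ_ij = (x_ij ⊗ I₄) β + b0_i + t_ij · b1_i + ε_ij,
    b0_i ~ N(0, diag ψ₀), b1_i ~ N(0, diag ψ₁), ε_ij ~ N(0, S_ij)

where x_ij contains the fixed-effect covariates and t_ij is the subperiod
midpoint year, centred at the grand mean. The registered model variants
are:

- **Model 3** (main): intercept + HPP indicator + Region + Time +
  Region × Time;
- **Model 4**: Model 3 + HPP × Region;
- **Model 5**: HPP effect stratified by the tercile HPP class
  (HPP × class replaces the single indicator).

Any other combination of the known terms can be passed as an explicit term
tuple, which is how unregistered variants are expressed. The HPP indicator
for a subperiod is 1 when the country's plan was implemented no later than
the subperiod's first year (two alternative readings — strictly-after and
any-overlap — are selectable, since the defining convention is ambiguous).

Estimation is maximum likelihood: β is profiled out by GLS for any ψ, and
the 8 log-variances are maximised by L-BFGS-B with ≥3 starts (a
moment-based start, a mid-scale start and a near-zero start); ties break
to the higher log-likelihood then the smaller parameter norm. Variances
whose optimum is on the boundary come back as exact zeros (values below
10⁻¹⁰ of the outcome scale are truncated). Nested variants are compared by
likelihood-ratio tests with df = 4 × (difference in fixed-effect terms).
City-specific curves are empirical-Bayes BLUPs,
b̂_i = Ψ Zᵢᵀ Vᵢ⁻¹ (y_i − X_i β̂); scenario curves toggle only the
fixed-effect HPP term while holding b̂_i fixed.

## Stage 3 — factual vs counterfactual attribution

For every unit, the factual (HPP as observed) and counterfactual (HPP
forced to 0) BLUP curves are each recentred at their own MMT (a switch
lets the counterfactual reuse the factual MMT). On days hotter than the
95th percentile of the location's full-period warm-season distribution,
the daily attributable fraction is (RR−1)/RR, floored at 0 when a noisy
curve dips below 1 (disable-able for diagnostics). Attributable numbers
(AN) are summed into:

- **HAF** — attributable % of all May–September deaths in the slice;
- **HAD** — annual attributable deaths per 100 000, using 2015 populations
  (AN / person-years × 10⁵);
- the scenario contrast over post-implementation subperiods:
  HAF change = (HAF_fact − HAF_cf)/HAF_cf × 100 (negative = protective),
  HAD difference = HAD_fact − HAD_cf, and total deaths avoided
  Σ(AN_cf − AN_fact).

Aggregation to country/region/class/overall pools raw AN and deaths before
forming fractions; an option additionally reports region rows as unweighted
means of country values, since both conventions appear in summary tables of
this kind. Uncertainty comes from 1000 Monte-Carlo draws of β from
N(β̂, V̂_β) (an exact PSD square root, so degenerate directions stay exact);
random effects are held at their point estimates by default, with a switch
to also draw them from their conditional covariance. CIs are the empirical
2.5th/97.5th percentiles, recomputing every scenario quantity per draw.

Because MMT recentring subtracts the curve's minimum, the estimated log-RR
at hot days is non-negative by construction; under a true null this imparts
a small upward bias to HAF in both scenarios which largely cancels in the
factual/counterfactual contrast.

## Synthetic data generator

The generator emulates the structure the analysis assumes, not European
climate realism:

- **Temperature**: seasonal cosine (region-specific mean/amplitude;
  Southern warmest) + AR(1) noise (sd 2.5 °C, autocorrelation 0.7) +
  Poisson-count heatwave episodes (default 1.5/summer, 3–6 days, half-sine
  excursions of ~5 °C).
- **Mortality**: log-linear baseline (default 20 deaths/day) with a
  winter-peaking seasonal cycle (amplitude 0.15, normalised to mean 1 over
  May–September so warm-season means match the baseline), day-of-week
  multipliers, and a lagged heat effect: the true log-RR is piecewise
  linear in the warm-season *percentile* — zero at and below the MMT
  percentile (default 75) and reaching the region's slope parameter at the
  99th percentile — distributed over lags 0–10 with geometric-decay weights
  summing to one. Slopes default to 0.25–0.40 across regions with a −0.03
  per decade trend. Counts are gamma-Poisson (NB2) with Var = ψ·mean
  (default ψ = 1.3), the standard generative stand-in for quasi-Poisson.
- **HPP**: each country's plan multiplies the above-MMT slope by
  `hpp_effect` (default 0.7, a 30% reduction) from January 1 of its
  implementation year — deliberately misaligned with the 3-year analysis
  blocks to stress the subperiod indicator. Catalogue scores are random
  0–2-weighted actions across 8 core elements, classed by terciles of the
  maximum score.

Because the lag weights sum to one, the true *overall cumulative* log-RR at
percentile p is exactly slope × s(p), so ground-truth HAF/HAD under both
scenarios have a closed form (`true_attribution`) computed with the same
day-selection and pooling rules as the estimation pipeline. What passing
recovery tests therefore show is that the three-stage machinery recovers a
known intervention effect embedded in realistically structured noise; they
do not show robustness to confounding (humidity, air pollution, demographic
shifts) or to exposure measurement error, none of which the generator
contains.

## Numerical choices and scales

- Quasi-Poisson IRLS: convergence tol 1e-8, 100 iterations; aliased design
  columns dropped by pivoted QR; a fit is discarded if cross-basis columns
  alias.
- Meta-likelihood: per-city marginal covariances assembled as
  blockdiag(S) + kron(J, diag ψ₀) + kron(ttᵀ, diag ψ₁), batched over cities
  with equal subperiod counts; log-determinants via `slogdet`. The
  variance optimisation uses the analytic gradient of the β-profiled
  likelihood (by the envelope theorem the profile gradient equals the
  partial derivative at the GLS β), verified against finite differences.
- MMT grid: 0.05-percentile steps in stage 1, 0.1 in the Monte-Carlo loop;
  ties break to the lowest temperature.
- Time variable: subperiod midpoint year, centred at the grand mean. Note
  that with diagonal Ψ the model family is not closed under shifts of Time
  (a shift induces intercept–slope random-effect covariance), so the centre
  is part of the model specification.
- Seeds: a master seed is split into per-stage seeds via
  `numpy.random.SeedSequence`; all outputs are byte-reproducible.

## Demonstration scales

Test and demonstration runs use reduced problem sizes chosen to exercise
every code path with adequate statistical power: the recovery experiment
uses 30 cities in 10 countries over 1993–2016 (8 subperiods) with
`hpp_effect = 0.7` and 250–1000 Monte-Carlo samples; the null experiment
uses 12 cities over 1999–2013 with `hpp_effect = 1`; LRT calibration uses
200 replicates of stage-2-level data at 30 cities × 8 subperiods. The full
study configuration (102 cities, 14 countries, 1990–2019, 10 subperiods)
is the generator default and runs in a few minutes.

## Known limitations

- Stage-3 CIs propagate stage-2 fixed-effect uncertainty (optionally also
  random-effect uncertainty) but treat stage-1 sampling error only through
  the within-unit covariances S_ij.
- The HAF floor at zero makes single-unit HAFs non-negative, which can
  bias very small HAFs upward; pooled contrasts are much less affected.
- Supplementary model variants beyond Models 3–5 have no registered form
  and must be supplied as explicit term tuples.
- The meta-regression assumes a diagonal random-effect covariance; no REML
  option is provided (ML is required for the LRTs), and no third
  country-level random effect is fitted.
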