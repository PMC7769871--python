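# Methods

## Quantification model

Antimicrobial usage is measured as numbers of Swiss defined daily doses.
For every prescription record (farm, product, quantity, age category,
year) the product is resolved into per-ingredient milligram amounts via
its registered concentrations; each ingredient contributes

```
nDDDch = amount_mg / (DDDch_mg_per_kg × standard_weight_kg)
```

where the defined dose is looked up by the (ingredient, route/formulation)
pair and the standard weight by the record's age category (ESVAC values
4 / 12 / 50 / 220 kg for piglets / weaners / fatteners / sows).
Combination products contribute one term per active ingredient; terms are
summed by farm × age category × antimicrobial class. Per-animal values
divide the category total by sows kept (sows) or animals produced per
year (other categories); the farm total per animal is the plain,
unweighted sum of the four category values.

Assumptions and scope:

- Allocation of prescriptions to age categories happens at the data
  source (farmer/veterinarian); the package never re-ages animals.
- Defined doses are keyed strictly by (ingredient, route). There is no
  cross-route fallback: a missing key is an error, because silently
  substituting a different formulation's dose would corrupt the metric.
- Ingredients dosed in international units must be entered in the
  formulary already converted to mg/kg; conversion factors are
  product-specific and out of scope.
- Used-daily-dose, treatment-incidence and mg/PCU metrics are out of
  scope; so is deriving DDDch values themselves — they are reference
  configuration, and the shipped demo formulary is explicitly
  illustrative.

Degenerate inputs: a category with positive usage but a zero census count
is undefined and reported as missing (NaN), never 0 or infinity, and it
propagates to that farm's total; zero usage over a zero count is 0. Farms
with zero usage stay in every denominator and statistic. Records outside
the configured study year are excluded with a logged count. Aggregation
is order-independent; population totals use compensated (fsum) summation.

## Statistical layer

- **Group comparison.** Kruskal–Wallis across the four age categories'
  per-animal values: midranks, the standard tie-correction divisor, H
  referred to chi-square with k−1 df. A permutation p-value is available:
  exact enumeration when the pooled sample has ≤ 10 observations,
  Monte-Carlo otherwise. All-identical data return H = 0, p = 1.
- **Post-hoc.** Pairwise two-sided tests with Bonferroni adjustment
  (raw p × k(k−1)/2, capped at 1). Default flavour is the unpaired
  rank-sum (Mann–Whitney) test, exact for small tie-free samples and
  asymptotic with continuity correction otherwise; a paired signed-rank
  flavour is offered because the four categories come from the same
  farms. Significance threshold 0.05.
- **Regressions.** Ordinary least squares with a two-sided slope t-test;
  adj R² = 1 − (1 − R²)(n−1)/(n−2). The suite runs the six within-herd
  pairs — sow→piglet, sow→weaner, sow→fattener, piglet→weaner,
  piglet→fattener, weaner→fattener (older category as predictor) — plus
  herd size (sows kept) → farm total per animal. A constant predictor is
  a degenerate-design error.
- **Diagnostics** (advisory only, never alter estimates): Shapiro–Wilk on
  residuals and a Breusch–Pagan-style LM test from the auxiliary
  regression of squared residuals on the predictor; identically-zero
  residuals are reported as not assessable.

## Synthetic cohort generator

The generator emulates the structure of farm-level monitoring data so the
pipeline is testable without confidential records:

- **Herd sizes**: sows ~ lognormal(μ=4.245, σ=0.52) truncated to
  [10, 220] and rounded, giving a mean near 77–79 and SD near 38–43;
  piglet/weaner/fattener annual throughput is 30 / 26 / 12 × sows with
  multiplicative lognormal noise (CV 0.20, a plausible between-farm
  spread for production ratios).
- **Usage marginals**: per-category nDDDch/animal/year is zero-inflated
  lognormal, capped at observed-scale maxima. Monitoring data show point
  masses at zero and heavy right tails, which this family reproduces with
  interpretable parameters. Defaults (zero probability, log-mean, log-sd,
  cap): piglets (0.10, −0.483, 1.507, 11.5), weaners (0.12, −0.114,
  1.414, 13.3), fatteners (0.30, −1.996, 2.162, 9.9), sows (0.05, 0.790,
  0.730, 13.8). The log-parameters were fitted to target medians and 75%
  quartiles of roughly 0.5/1.5, 0.7/2.0, 0.04/0.3 and 2.1/3.5; the
  fattener zero probability must exceed 0.25 because its lower quartile
  is zero.
- **Dependence**: a latent Gaussian factor model. Each category's latent
  standard-normal score loads on the herd-size factor with loading
  `herd_usage_corr`; the piglet residual is linear in the sow residual
  with correlation `sow_piglet_corr`; scores are mapped through the
  marginal quantile function. This separates dependence strength from
  marginal shape and injects the herd-size effect on the farm-total
  scale. Weaner/fattener cross-links beyond the shared herd factor are
  deliberately absent (they are reported as non-significant in field
  data).
- **Calibration**: `scripts/calibrate_synthetic.py` sweeps the two link
  parameters and measures, over 200 replicate 71-farm cohorts, the mean
  recovered adjusted R² of the piglet-on-sow and total-on-herd-size
  regressions. The shipped defaults `sow_piglet_corr = 0.50`,
  `herd_usage_corr = 0.19` give means near 0.19 and 0.06; observed-scale
  R² is attenuated relative to the latent correlations by the
  zero-inflation, caps and skew, which is why the calibrated latent
  values exceed the target R².
- **Record emission** inverts the quantification formula: each farm ×
  category target is split across antimicrobial classes by
  Dirichlet-jittered category-specific weights (penicillin-dominated
  everywhere except weaners, which lean on sulfonamide/tetracycline
  premixes; overall HPCIA share lands near 20% of doses), and each class
  share is converted into a demo-product quantity. Quantifying the
  emitted records therefore reproduces the latent targets to floating-
  point precision — the pipeline's end-to-end identity, asserted in
  tests over 100 seeds.

What the generator does **not** emulate: treatment indications and
courses, seasonality, within-year dynamics, biosecurity or management
covariates, realistic product portfolios per farm, or the exact
herd-size/usage tail behaviour of any particular national dataset.
Passing calibration tests shows the pipeline recovers injected structure
at study scale; it does not validate the generator as a model of any real
population.

## Numerical and design choices

- Percent shares are computed on unrounded totals (they sum to 100 to
  1e-9) and displayed with half-up integer rounding.
- Quartiles default to linear interpolation between order statistics
  (type 7); type 6 (`weibull`) is available. CIs are t-based; a single
  observation yields an undefined CI (NaN).
- Determinism: every stochastic step flows through an explicit integer
  seed; identical inputs and configuration produce byte-identical output
  files.
- Problem sizes in the shipped tests and acceptance script — 200
  replicate cohorts for calibration means, 100 seeds for the round-trip
  identity, 1e5 permutations for the Monte-Carlo oracle — were chosen as
  the smallest sizes at which the Monte-Carlo error of the checked
  quantities is comfortably below the assertion tolerances.

## Known limitations

- The demo formulary's doses are placeholders; real analyses must supply
  the national DDDch registry.
- Long-acting injectables can only be represented as distinct route
  entries; there is no duration-factor mechanism.
- The pairwise post-hoc flavour used by the original monitoring analyses
  (paired vs. unpaired) is not documented in the field; both are offered,
  default unpaired.
- Multivariable or mixed-effects modelling of usage drivers is out of
  scope.
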