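# Methods

## The question and the simulation model

`truthbench` asks whether conventional validation measures for binary risk
prediction can identify the *outcome-generating* ("true") model among
proxy candidates fitted to the same data. Everything is simulated, so the
true model is known exactly and every comparison is against ground truth.

Outcomes follow a logistic model: y ~ Bernoulli(expit(β₀ + Σ βₖ xₖ)), with
an optional product interaction for two-predictor scenarios. Causal
predictors are standard normal (continuous) or Bernoulli (binary);
effects βₖ are on the log-odds scale. All randomness flows from
`numpy.random.SeedSequence`: each scenario carries a derived child seed,
and each replicate uses the spawn key `(rep_index, attempt)`, so any
subset of the grid can be run in any order (or in parallel) with
bit-identical results.

## Scenario grids

A scenario fixes the true model, predictor kinds, proxy correlations,
sample size, split and replicate count. The default grids are:

- **Univariate** (n = 15,000 per dataset, 84 scenarios):
  β₁ ∈ {log 1, log 1.3, log 1.7, log 2, log 2.5, log 3, log 4} ×
  β₀ ∈ logit{0.1, 0.2, 0.3, 0.5} × predictor kind, with prevalence
  {0.3, 0.5} as an extra factor in the binary arm only (a prevalence
  factor is meaningless for a continuous predictor, so the two arms are
  built as separate Cartesian products and concatenated).
- **Multivariate** (n = 3,000 per dataset, 864 scenarios):
  β₁, β₂ ∈ {log 1.3 … log 4} (the univariate levels without the exact
  null — a two-predictor causal model with both effects null is not a
  meaningful causal model, and the heuristic shrinkage factor of a
  null fit is a heavy-tailed ratio statistic whose grid mean diverges),
  β₀ ∈ logit{0.1, 0.2, 0.3, 0.5}, kinds continuous+continuous or
  continuous+binary (prevalence 0.3), causal correlation ∈ {0, 0.3, 0.5}.

Every factor level is overridable through the config mapping accepted by
`build_grid` (and the YAML file accepted by the CLI); grid size is always
the product of the level counts.

**Known ceiling.** With standard-normal predictors and effects capped at
log 4, the achievable true-model C statistic tops out near 0.81
(univariate) — discrimination is monotone in sd(βx)/σ of the latent
logistic noise. Grid-mean C under the default design is therefore ~0.61
(univariate) and ~0.76 (multivariate). Scenario families with stronger
discrimination require wider predictor scales or larger effects than the
default design admits; both can be configured, but are deliberately not
the default.

## Proxy construction

Each dataset carries non-causal proxies: one independent proxy of the
causal predictor's kind plus one correlated proxy per requested ρ
(univariate: ρ ∈ {0.3, 0.5, 0.8}; multivariate: a single ρ = 0.5 serves
the catalog, plus independent continuous/binary columns and a proxy of
the second predictor). Correlations are targeted on the *observed*
Pearson scale:

- continuous–continuous: z = ρ·standardised(target) + √(1−ρ²)·ε, exact in
  expectation;
- pairs involving a binary variable: a latent-Gaussian threshold
  construction. The latent correlation r is solved so the thresholded
  variables hit ρ — closed form r = ρ√(pq)/φ(c) for normal-vs-indicator,
  Brent root-finding on the bivariate-normal orthant probability for
  indicator-vs-indicator. A binary *target* is first mapped back to a
  latent normal by a truncated-normal draw conditional on the indicator.

Attainability is enforced: a point-biserial correlation is bounded by
φ(c)/√(pq) (≈ 0.80 at prevalence 0.5, 0.76 at 0.3), so e.g. ρ = 0.8
between mixed kinds raises an error rather than silently under-shooting.
Same-kind pairs at matched prevalence are feasible at every default ρ.

## Candidate catalog

Univariate (10): `TrueModel`; `FlipCoin` (constant risk 0.5 — the only
definition consistent with its exact Brier score 0.25 and AUC 0.5);
`AddIndModel`/`Add03Model`/`Add05Model`/`Add08Model` (true model plus one
noise or correlated proxy); `AICTrueModel` (bidirectional stepwise AIC
over the causal predictor and all proxies, started from the full model,
everything removable); `AICAddModel` (same with the causal predictor
excluded from the search); `ShrinkTrueModel`/`ShrinkAddModel` (heuristic
shrinkage applied to the true model / the full proxy model).

Multivariate (12): the true and flip-coin references; `Variable1`/
`Variable2` submodels; `AddIndCont`/`AddCorrCont`/`AddCat` (true model
plus one extra variable of the named kind); and four "missing variable 1"
models in which x₁ is dropped and replaced by its independent proxy, its
correlated proxy, the second predictor's correlated proxy, or
combinations of these. The last entry combines all three replacement
proxies. The catalog is a plain list of `CandidateSpec`s and fully
config-extensible.

Fitting is maximum-likelihood IRLS (statsmodels GLM, binomial family,
100 iterations). Coefficients beyond ±15 log-odds are treated as
(quasi-)separation: capped, flagged non-converged, and the log-likelihood
re-evaluated at the capped coefficients so downstream measures still
compute. Stepwise AIC uses AIC = −2ℓ + 2(df+1), takes the single best
add/remove move per step, breaks ties by variable name, and may reduce to
the intercept-only model. Shrinkage multiplies the slopes by
γ = (χ² − df)/χ² and refits the intercept with the shrunken linear
predictor as a fixed offset; the training log-likelihood is recomputed at
the final coefficients, so the reported shrinkage factor of a shrunken
candidate refers to the model actually used.

## Measure panel: dialects and conventions

All 25 measures are computed on test-set predictions (clipped to
[1e−10, 1−1e−10]); only the global shrinkage factor comes from the
training fit, since it quantifies overfitting.

- **U, D, Q** use the validation-probability dialect. With the free
  logistic recalibration logit P(y=1) = a + b·logit(p̂):
  D = (χ²_D − 1)/n against the test null model and U = (χ²_U − 2)/n
  against the identity calibration (a=0, b=1); a degenerate (constant-p̂)
  prediction set has one free parameter, so 1 is subtracted instead of 2.
  Q = D − U holds exactly by construction.
- **Calibration-in-the-large OR** is predicted odds over observed odds.
- **Emax/E-mean families**: deviations |q − ĉ(q)| of the recalibration
  curve, with q over the observed prediction range ("_ab": max over the
  interval, mean over the observed p̂) or over the fixed grid
  0.001(0.001)0.999 ("_01"). Degenerate predictions collapse the curve to
  the observed rate: both Emax values equal |p̂ − rate| and the E-means
  are reported missing.
- **Eavg/ECI** use a LOWESS smoother of y on p̂ (span 2/3, zero
  robustness iterations); ECI is ×100 (per-cent² scale). When a
  tie-cluster of identical predictions fills the whole bandwidth window —
  routine with a single binary predictor — the local fit is ill-posed and
  the implementation substitutes the exact tricube limit for separated
  clusters, the per-value event rate.
- **Pseudo-R²**: Cox–Snell, Nagelkerke, McFadden (and adjusted, with k =
  non-intercept terms), Aldrich–Nelson, Veall–Zimmermann, Efron,
  McKelvey–Zavoina (var(logit p̂), ddof 1, against π²/3), Tjur. IDI
  against the null model equals Tjur's R² identically and serves as an
  internal consistency check.
- Undefined cases (single-class outcome, coin-flip shrinkage factor)
  yield NaN for that measure only, never a panel failure.

## Aggregation and reporting

Differences are candidate − true within the same replicate. Summaries
pool all scenario × replicate values per (measure, candidate) cell —
equal replicate counts per scenario make this identical to equal-weight
scenario pooling — and report the mean with the empirical 2.5th/97.5th
percentiles (linear-interpolation quantiles). Rounding to two decimals
happens only at serialisation, preserving "−0.00". Stepwise runs that
happen to reduce to the true model are retained (self-comparisons with
difference 0), mirroring their small share of runs. Boxplots draw one box
per candidate in catalog order with a zero reference line, and the
plotting routine returns the exact arrays drawn so tests can verify no
silent transformation.

## Problem sizes used by the tests and the acceptance script

The checked-in tests and `scripts/acceptance.py` run desk-scale
subsamples chosen as the package's own defaults: 50–60 scenarios per arm
× 10 replicates at the full per-dataset sample sizes (univariate 15,000;
multivariate 3,000), which stabilises the grid means reported (their
Monte-Carlo s.e. is well inside the tolerances tested) while completing
in about a minute per arm. Unit tests use small bespoke scenarios
(n = 400–600) plus closed-form and brute-force oracles: O(n²) pair counts
for C and g-index, direct likelihood maximisation for the logistic fits,
and a coarse-to-fine 2-D likelihood grid search for the recalibration.

## What the generator does and does not emulate

It emulates the statistical core of clinical tabular data: mixed
continuous/binary predictors, realistic event rates (10–50%), modest
effect sizes, correlated non-causal covariates, and train/test splitting.
It does not emulate survey weights, missing data, measurement error,
non-linear or time-varying effects, survival outcomes, or sampling bias.
Passing tests therefore show that the *measures* behave as analysed under
a correctly specified logistic world — not that real cohorts satisfy
those assumptions.

## Known limitations

- The discrimination ceiling of the default grids (above): headline
  grid-mean C sits below levels reachable only with wider predictor
  scales.
- The grid mean of the shrinkage-factor *difference* is unstable
  whenever near-null scenarios are present (ratio statistic); quantile
  summaries remain meaningful, and the shrinkage level of well-specified
  models is stable (≈ 0.99 at multivariate n = 3,000).
- Stepwise AIC retains a pure-noise predictor with probability
  P(χ²₁ > 2) ≈ 0.157 per candidate variable; "drops noise" statements
  hold in that stochastic sense, not surely.
- LOWESS-based measures inherit smoother artefacts for few-valued
  prediction distributions; the per-value-rate substitution removes the
  ill-posed case but is exact only for well-separated clusters.
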