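# truthbench

Can conventional performance measures single out the *outcome-generating*
model among plausible proxy models?

Clinical risk prediction models for binary outcomes are routinely compared
on discrimination (e.g. the C statistic), calibration (e.g. calibration-in-
the-large, Harrell's E-family) and overall-performance measures (Brier
score, pseudo-R²), and the "best performing" model is the one applied in
practice. `truthbench` is a Monte-Carlo benchmark for a sharper question:
if the data really were generated by a known logistic model — the *true
model* — would these measures identify it? It is aimed at biostatisticians
and methods researchers studying model validation, selection and
misspecification.

## What it does

The outcome is simulated from a causal logistic model

```
y_i ~ Bernoulli(p_i),   logit(p_i) = β₀ + β₁ x_{i1} [+ β₂ x_{i2}]
```

with continuous (standard normal) or binary (Bernoulli) causal predictors
and effects β on the log-odds scale spanning odds ratios 1–4. Non-causal
*proxy* predictors — independent, or correlated with a causal predictor at
Pearson ρ ∈ {0.3, 0.5, 0.8} via a latent-Gaussian threshold construction —
are appended but never used in the outcome formula. Each dataset is split
80/20 into training and testing halves.

A catalog of named candidate models is then fit on the training half and
scored on the testing half: the true model itself; a "flip a fair coin"
reference (constant risk 0.5); the true model augmented with independent
or correlated noise (`AddIndModel`, `Add03Model`, …); bidirectional
stepwise-AIC selections with the causal predictor available
(`AICTrueModel`) or withheld (`AICAddModel`); and post-hoc shrinkage
(`ShrinkTrueModel`, `ShrinkAddModel`) using van Houwelingen's heuristic
shrinkage factor γ = (χ² − df)/χ². The multivariate catalog adds
single-predictor submodels and "missing variable 1" replacements (12
candidates in all; 10 univariate).

Every candidate is scored with a 25-measure panel — AUC, Somers' Dxy,
g-index, the U/D/Q likelihood indices, calibration-in-the-large OR,
Emax/E-mean error families, LOWESS-based Eavg and ECI, Brier score, nine
pseudo-R² flavours, the shrinkage factor, and IDI against the null model —
and differenced against the true model of the same replicate
(candidate − true). Grid summaries report `mean (2.5th, 97.5th percentile)`
per measure × candidate.

## Worked example

```python
import numpy as np
import truthbench as tb

spec = tb.ScenarioSpec(
    scenario_id="demo", arity="univariate", predictor_kinds=("continuous",),
    beta0=-0.85, betas=(float(np.log(2)),), n_total=15_000, n_reps=3, seed=11)
records = tb.run_scenario(spec)
table = tb.format_summary(records)
print(table.loc[["AUC", "U", "OR_caliLarge", "brierScore",
                 "GlobalShrinkageFactor"],
                ["TrueModel", "FlipCoin", "AddIndModel", "AICAddModel"]])
```

prints

```
                                TrueModel              FlipCoin           AddIndModel           AICAddModel
measure
AUC                     0.70 (0.69, 0.71)  -0.20 (-0.21, -0.19)  -0.00 (-0.00, -0.00)  -0.03 (-0.03, -0.03)
U                      0.00 (-0.00, 0.00)     0.14 (0.13, 0.15)  -0.00 (-0.00, -0.00)  -0.00 (-0.00, -0.00)
OR_caliLarge            1.03 (0.99, 1.06)     1.18 (1.12, 1.22)   -0.00 (-0.00, 0.00)   -0.00 (-0.00, 0.00)
brierScore              0.19 (0.19, 0.20)     0.06 (0.05, 0.06)     0.00 (0.00, 0.00)     0.01 (0.01, 0.01)
GlobalShrinkageFactor   1.00 (1.00, 1.00)                    NA  -0.00 (-0.00, -0.00)  -0.00 (-0.00, -0.00)
```

The `TrueModel` column shows raw measure values; every other column shows
differences to the true model. Reading it: the true model discriminates
(AUC 0.70) and is calibrated (U ≈ 0, OR ≈ 1). The coin flip is clearly
worse (AUC −0.20, U +0.14). But the model with an extra pure-noise
predictor is *indistinguishable* from the true model on every measure
(all −0.00), and even the stepwise model denied the causal predictor —
forced to work with correlated proxies only — loses just 0.03 of AUC.
That is the benchmark's central point: these measures separate the true
model from nonsense, but not from proxy models.

A full grid run, with report tables and per-measure boxplots of the
differences, is available from the CLI:

```sh
truthbench run --arity univariate --seed 0 --reps 2 --scenario-fraction 0.05 --out results/
truthbench plot results/records.csv --measure AUC --out results/
```

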