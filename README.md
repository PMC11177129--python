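# bivlogit

Joint regression analysis of two correlated binary survey outcomes — the
motivating application is early marriage (marital union before age 18) and
school dropout among girls, observed in a DHS-style multistage survey —
together with the zone-level spatial statistics that typically precede such
a model. The package is aimed at biostatisticians and epidemiologists who
need a bivariate binary model with cluster random effects and a spatial
auto-covariate, plus a fully synthetic data generator so that every stage
can be exercised and validated without access to restricted microdata.

## The model

Two binary outcomes (Y1, Y2) are modelled jointly through three linear
predictors (the Plackett/Dale bivariate binary logistic model):

    logit π1(x) = xᵀβ1          (marginal logit of Y1)
    logit π2(x) = xᵀβ2          (marginal logit of Y2)
    log  ψ(x)  = xᵀβ3          (log odds ratio of Y1 and Y2)

The four joint cell probabilities follow from (π1, π2, ψ) by solving the
Plackett quadratic

    π11 = [S − √(S² − 4ψ(ψ−1)π1π2)] / (2(ψ−1)),   S = 1 + (π1+π2)(ψ−1)

(π11 = π1π2 at ψ = 1), constrained to the Fréchet interval
[max(0, π1+π2−1), min(π1, π2)]. Parameters are estimated by (optionally
survey-weighted) maximum likelihood over the multinomial cell likelihood,
with Wald tests from the inverse observed information.

The multilevel extension adds a bivariate normal cluster random intercept
(b1j, b2j) ~ N(0, Σ) to the two marginal predictors and integrates it out
with two-dimensional adaptive Gauss–Hermite quadrature (mode-and-curvature
standardized). A spatial auto-covariate

    Si = Σj wij yj / Σj wij

(the neighbor-average zone rate of each outcome, wij binary contiguity)
can enter each outcome's fixed part as a zone-level predictor. Model
variants (level-1 predictors only; level-1 + level-2; cross-level
interactions) are compared by AIC.

The spatial module provides contiguity weights, survey-weighted zone
rates, global Moran's I (analytic and permutation inference), Getis-Ord
Gi\* hot/cold spots, Local Moran (LISA) cluster/outlier typing, and
ordinary kriging of zone rates with a WLS-fitted exponential
semivariogram. The descriptive module provides weighted prevalence, the
2×2 joint/marginal table with its odds ratio, and chi-square screening of
predictors against the 4-level joint outcome.

## Worked example

```python
import numpy as np
from bivlogit import (plackett_joint, odds_ratio_2x2,
                      default_config, simulate_dataset,
                      ModelSpec, fit_dale)

# A published 2x2 table: cells (n11, n10, n01, n00) = (1308, 388, 907, 336)
print(odds_ratio_2x2(1308, 388, 907, 336))   # 1.2488434740108434
jp = plackett_joint(pi1=0.577, pi2=0.754, psi=1.249)
print(round(jp.p11, 3))                      # 0.445

# Synthetic three-level survey with known truth
records, zones, truth = simulate_dataset(default_config(seed=1))
fit = fit_dale(records, ModelSpec(formula1=["residence", "wealth"],
                                  formula2=["residence", "wealth"],
                                  reference_levels={"wealth": "richest",
                                                    "residence": "urban"}))
print(round(float(np.exp(fit.params.beta3[0])), 3))
```

Running this prints `1.2488434740108434`, `0.445` and `1.42`: the
empirical odds ratio of the printed table, the joint probability that both
outcomes occur implied by its margins and odds ratio, and the estimated
outcome odds ratio ψ̂ on one simulated dataset (generating value 1.4).

The full pipeline (simulate → describe → spatial → model ladder →
diagnostics → report) runs from the command line:

```
bivlogit all --config examples/config.yaml --seed 7 --out-dir out/demo_run
```

writing `table2_joint_marginal.csv`, `table1_chisq_screen.csv`,
`global_moran.csv`, `spatial_zone_stats.csv`, kriging surfaces, per-variant
coefficient tables, `model_comparison.csv`, `odds_ratio_report.csv`,
residual diagnostics, and a run manifest. Reruns with the same config and
seed are byte-identical.

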