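# Methods

## The Plackett/Dale bivariate binary model

Two binary outcomes per subject are described by their two marginal logits
and the log odds ratio between them, each a linear function of covariates.
Given (π1, π2, ψ) the joint cell probabilities are unique: π11 solves the
quadratic ψ = π11π00/(π10π01) with margins fixed. For ψ ≠ 1 we take

    π11 = [S − √(S² − 4ψ(ψ−1)π1π2)] / (2(ψ−1)),  S = 1 + (π1+π2)(ψ−1),

the same expression for ψ > 1 and ψ < 1: it is the unique root inside the
Fréchet interval in both branches, which the test suite confirms by a
round-trip property sweep (solve, recompute the OR, compare) across
ψ ∈ [1e-3, 1e3] and margins in [0.01, 0.99]. Near ψ = 1 (|ψ−1| < 1e-9) we
switch to the independence product to avoid 0/0; a negative discriminant
(possible only through rounding) is clamped to zero with a logged warning,
and the root is clipped to the Fréchet interval.

The likelihood is multinomial over the four cells. Survey weights enter as
a pseudo-log-likelihood Σ wᵢ log π_cell(i); reported standard errors are
model-based (inverse observed information), not design-based — no
linearization or replicate weights. Optimization is BFGS with the analytic
gradient (closed-form Plackett derivatives; ∂π11/∂ψ by implicit
differentiation of π11π00 = ψπ10π01). Numerical choices: probability clamp
1e-12; gradient tolerance 1e-8 with a fallback acceptance when the final
gradient is below 1e-4 in max norm (BFGS occasionally reports "precision
loss" while already at the optimum to well below the standard-error
scale); Hessian by central differences with step 1e-5·(1+|θ|).

β3 is intercept-only by default (a single dependence parameter ψ);
covariates may enter it through `formula3`. Categorical covariates are
reference-coded with user-settable reference levels, defaulting to the
lexicographically first category. Records with unseen categories at
prediction time raise an error naming the covariate.

## Multilevel extension

Each cluster j adds a bivariate normal random intercept (b1j, b2j) with
covariance Σ to the two marginal predictors; the cluster's marginal
likelihood integrates the conditional Plackett likelihood over (b1, b2).
Integration is adaptive Gauss–Hermite quadrature: per cluster, a damped
Newton search (vectorized across clusters, analytic gradient,
finite-difference curvature) finds the posterior mode and negative
Hessian; nodes are centered at the mode and scaled by the Cholesky factor
of the inverse curvature. The default is 7 points per dimension (49
nodes), a standard accuracy/cost compromise for binary-response mixed
models. For clusters holding only one or two binary records the posterior
is wide and visibly non-Gaussian, and ~1e-6 absolute accuracy requires a
finer rule; the validation suite compares a 15-point rule against
brute-force 2-D trapezoid integration on a 400×400 grid over [−8, 8]².
With Σ = 0 the integral degenerates and the code returns the single-level
conditional likelihood exactly.

Variance components are optimized on a log-Cholesky scale (log-diagonal,
free off-diagonal), which enforces positive semidefiniteness without
constraints; their standard errors on the natural scale come from the
delta method. Wald p-values for variance components are boundary tests and
are logged with a caveat — they are conservative at best. The outer
optimizer is L-BFGS-B with forward-difference gradients (step 1e-5);
per-cluster modes are warm-started between objective evaluations, which
keeps each evaluation at one or two Newton steps.

Model variants: `random_intercept_L1` uses the level-1 formulas only;
`random_intercept_L1L2` appends the declared level-2 (cluster/zone-level)
terms; `random_intercept_crosslevel` additionally adds product-indicator
interactions between declared (level-1 × level-2) pairs;
`random_slope` is a deliberate stub that raises unless forced, because
random slopes in this model family are notoriously non-convergent at
realistic cluster sizes. AIC = −2ℓ + 2k with k = fixed effects + 3
variance parameters; `compare_models` ranks converged fits by AIC, breaks
ties by fewer parameters, and ranks non-converged fits last.

The spatial auto-covariate Si of each outcome is the contiguity-weighted
average of neighboring zones' outcome rates (self excluded, since
w_ii = 0), constant within zone, entered as one fixed-effect column per
outcome. An island zone takes the global mean rate as its Si.

## Spatial statistics

Weights are rook-contiguity by construction of the synthetic lattice;
Moran's I and Local Moran use row-standardized weights, Gi\* uses binary
weights with self-inclusion — the conventional pairings. Global Moran's I
reports the randomization-variance analytic z (two-sided p) and a
one-sided (positive autocorrelation) permutation pseudo p,
(count + 1)/(n_perm + 1), with n_perm defaulting to 999 and a mandatory
seed. Local Moran uses conditional permutation (hold zone i fixed, sample
its neighbors from the remaining values) and types zones HH/LL/HL/LH by
the signs of the standardized value and its spatial lag, NS above the 0.05
pseudo-p threshold. Gi\* bins |z| at 1.645/1.960/2.576 (90/95/99%
hotspot/coldspot categories); a zone whose neighborhood spans every zone
has an undefined (NaN) Gi\*. No multiple-testing correction is applied
across zones by default. Constant rate vectors raise (zero variance);
island zones are excluded from the autocorrelation statistics with a
warning.

Ordinary kriging fits an exponential semivariogram
γ(h) = nugget + sill·(1 − e^(−h/range)) to the binned empirical
semivariogram by weighted least squares (Cressie weights √N(h)/γ²),
with all three parameters bounded below by zero, then solves the standard
constrained system per grid node; weights sum to one, and with a zero
nugget predictions at observed centroids interpolate exactly. Estimating
a variogram needs at least 5 sites; the kriging system itself is solved
for any n ≥ 2 when an explicit variogram model is supplied. Coordinates
are planar throughout; duplicate centroids raise.

## Synthetic data generator

The generator emulates a three-level DHS-style sample: zones on a regular
lattice with rook contiguity, clusters nested in zones, women nested in
clusters. Per cluster, (b1, b2) is bivariate normal; per woman,
categorical covariates are drawn at their declared level (woman, cluster
or zone), a sampling weight is uniform on `weight_range`, and one of the
four outcome cells is drawn from the Plackett joint probabilities at
η1 = xᵀβ1 + b1 + zone effect, η2 likewise, ψ = exp(log_psi). Zone effects
follow a proper CAR-style scheme — effects = zone_sd·L·z with L the
Cholesky factor of (D − ρA)⁻¹ rescaled to unit average diagonal — so
`zone_sd` is the average marginal SD of the zone shift whatever ρ. By
default the same zone draw shifts both outcomes (a shared spatial
confounder, the minimal structure under which the auto-covariate matters
for both outcomes); `zone_effects_shared=False` draws them independently.
Weights are non-informative by default; `informative_weights=True` ties
them monotonically to the zone effect for robustness experiments.

Defaults mirror the motivating study's scale: 74 zones on a 9×9 lattice,
9 clusters per zone, 5 women per cluster (~3,330 women ≈ the study's
3,091), baseline margins near 0.58/0.75, outcome odds ratio 1.4,
random-intercept covariance (0.393, 0.518, 0.071), zone_sd 0.35 with
ρ = 0.8 (enough spatial signal for a clearly positive Moran's I),
weights uniform on (0.5, 2).

What the generator does **not** emulate: two-stage
probability-proportional-to-size sampling (only unequal weights), real
polygon contiguity or geography, covariate–zone confounding, missing
data, or informative cluster sizes. Passing tests therefore demonstrate
correctness of the estimators under the stated generating mechanism, not
robustness to those real-data features.

## Validation design and problem sizes

Every closed-form operation is checked against hand-computed or printed
values; every spatial statistic against naive double-loop
reimplementations (agreement to 1e-12); the quadrature against brute-force
grid integration (1e-6); the single-level fit against independent
univariate logistic fits at ψ = 1 and against its own generator at
n = 20,000. Multilevel recovery uses a 60-zone × 5-cluster × 20-woman
design (6,000 women, 300 clusters) with ψ = 1.4 and variance components
(0.4, 0.5, 0.07), 20 replicates: mean absolute bias of fixed effects
≤ 0.1 and variance components within 3 empirical SDs. The AIC ladder check
uses a 24-zone × 4-cluster × 10-woman design with a genuine cluster-level
effect (coefficients 0.8/0.6) and a useless 3-level × 2-level cross-level
interaction, 20 replicates, 5 quadrature points — sizes chosen to keep
the full suite fast while leaving the selection signal unambiguous.
Permutation calibration uses 200 null replicates at n_perm = 199 on a
4×4 lattice.

## Known limitations

- Standard errors ignore the survey design (weighted pseudo-likelihood
  with model-based information); no weight-scaling correction at level 1.
- Zones enter only through the auto-covariate and descriptive statistics;
  there is no third random level.
- The random-slope variant is a stub; cross-level interactions are limited
  to product indicators of declared pairs.
- Local-statistic p-values are unadjusted across zones by default.
- Kriging is isotropic ordinary kriging with an exponential model only.
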