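"""Single-level bivariate binary logistic regression (Plackett/Dale model).

Two correlated binary outcomes are modelled jointly through three linear
predictors: the two marginal logits and the log odds ratio,

    logit pi1(x) = x' beta1
    logit pi2(x) = x' beta2
    log  psi(x)  = x' beta3

The four joint cell probabilities (pi00, pi01, pi10, pi11) are recovered from
(pi1, pi2, psi) by solving the Plackett quadratic constrained to the Frechet
bounds, and the parameters are estimated by (optionally survey-weighted)
maximum likelihood over the multinomial cell likelihood.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

logger = logging.getLogger(__name__)

_PROB_CLAMP = 1e-12


# ---------------------------------------------------------------------------
# Joint-probability solver
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class JointProbability:
    """The 2x2 joint cell probabilities of two binary outcomes.

    Cells are indexed (y1, y2); ``p11`` is P(Y1=1, Y2=1).  ``pi1`` and
    ``pi2`` are the marginal success probabilities and ``psi`` the odds
    ratio p11*p00 / (p10*p01).
    """

    p00: float
    p01: float
    p10: float
    p11: float
    pi1: float
    pi2: float
    psi: float

    def as_array(self) -> np.ndarray:
        return np.array([self.p00, self.p01, self.p10, self.p11])


def plackett_p11(pi1, pi2, psi):
    """Vectorized P(Y1=1, Y2=1) for given margins and odds ratio.

    For psi != 1 takes the root

        p11 = [S - sqrt(S^2 - 4 psi (psi-1) pi1 pi2)] / (2 (psi-1)),
        S = 1 + (pi1 + pi2)(psi - 1),

    which is the unique root inside the Frechet interval
    [max(0, pi1+pi2-1), min(pi1, pi2)] for both psi > 1 and psi < 1.
    """
    pi1 = np.asarray(pi1, dtype=float)
    pi2 = np.asarray(pi2, dtype=float)
    psi = np.asarray(psi, dtype=float)
    if np.any(psi <= 0):
        raise ValueError("odds ratio psi must be strictly positive")
    if np.any((pi1 <= 0) | (pi1 >= 1) | (pi2 <= 0) | (pi2 >= 1)):
        raise ValueError("marginal probabilities must lie strictly in (0, 1)")

    pi1, pi2, psi = np.broadcast_arrays(pi1, pi2, psi)
    p11 = np.empty(pi1.shape, dtype=float)

    near_one = np.abs(psi - 1.0) < 1e-9
    p11[near_one] = pi1[near_one] * pi2[near_one]

    g = ~near_one
    if np.any(g):
        a, b, r = pi1[g], pi2[g], psi[g]
        s = 1.0 + (a + b) * (r - 1.0)
        disc = s * s - 4.0 * r * (r - 1.0) * a * b
        if np.any(disc < 0):
            logger.warning("Plackett discriminant < 0 in %d cells; clamped to 0",
                           int(np.sum(disc < 0)))
            disc = np.maximum(disc, 0.0)
        p11[g] = (s - np.sqrt(disc)) / (2.0 * (r - 1.0))

    lo = np.maximum(0.0, pi1 + pi2 - 1.0)
    hi = np.minimum(pi1, pi2)
    return np.clip(p11, lo, hi)


def plackett_dp11(pi1, pi2, psi):
    """Partial derivatives (d p11 / d pi1, d p11 / d pi2), vectorized.

    Closed form from differentiating the quadratic root; at psi = 1 the
    derivatives reduce to (pi2, pi1).
    """
    pi1 = np.asarray(pi1, dtype=float)
    pi2 = np.asarray(pi2, dtype=float)
    psi = np.asarray(psi, dtype=float)
    pi1, pi2, psi = np.broadcast_arrays(pi1, pi2, psi)
    d1 = np.empty(pi1.shape)
    d2 = np.empty(pi1.shape)
    near_one = np.abs(psi - 1.0) < 1e-9
    d1[near_one] = pi2[near_one]
    d2[near_one] = pi1[near_one]
    g = ~near_one
    if np.any(g):
        a, b, r = pi1[g], pi2[g], psi[g]
        s = 1.0 + (a + b) * (r - 1.0)
        disc = np.maximum(s * s - 4.0 * r * (r - 1.0) * a * b, 1e-300)
        q = np.sqrt(disc)
        d1[g] = 0.5 * (1.0 - (s - 2.0 * r * b) / q)
        d2[g] = 0.5 * (1.0 - (s - 2.0 * r * a) / q)
    return d1, d2


def plackett_joint(pi1: float, pi2: float, psi: float) -> JointProbability:
    """Solve for the 2x2 joint distribution given margins and odds ratio."""
    p11 = float(plackett_p11(pi1, pi2, psi))
    p10 = pi1 - p11
    p01 = pi2 - p11
    p00 = 1.0 - pi1 - pi2 + p11
    return JointProbability(p00=p00, p01=p01, p10=p10, p11=p11,
                            pi1=float(pi1), pi2=float(pi2), psi=float(psi))


def odds_ratio_2x2(n11, n10, n01, n00) -> float:
    """Empirical odds ratio n11*n00 / (n10*n01) of a 2x2 table.

    Returns ``inf`` when the denominator is zero but the numerator is not;
    raises when both vanish (0/0 undefined).
    """
    if min(n11, n10, n01, n00) < 0:
        raise ValueError("cell counts must be nonnegative")
    num = n11 * n00
    den = n10 * n01
    if den == 0:
        if num == 0:
            raise ValueError("odds ratio undefined: 0/0 table")
        return float("inf")
    return num / den


# ---------------------------------------------------------------------------
# Model specification and design matrices
# ---------------------------------------------------------------------------

@dataclass
class ModelSpec:
    """Which covariates enter each of the three linear predictors.

    ``formula3`` may be empty, in which case the log odds ratio is
    intercept-only (a single dependence parameter, as in a standard Dale
    fit).  Reference levels default to the lexicographically first category
    of each categorical covariate unless overridden.
    """

    formula1: list[str] = field(default_factory=list)
    formula2: list[str] = field(default_factory=list)
    formula3: list[str] = field(default_factory=list)
    reference_levels: dict[str, str] = field(default_factory=dict)
    use_weights: bool = False
    outcome1: str = "y1"
    outcome2: str = "y2"
    weight_col: str = "weight"


@dataclass
class DesignInfo:
    """Frozen encoding of one linear predictor's design matrix."""

    terms: list[str]
    columns: list[str]
    # covariate -> ordered non-reference levels (categoricals only)
    levels: dict[str, list[str]]
    reference: dict[str, str]


def build_design(df: pd.DataFrame, terms: list[str],
                 reference_levels: dict[str, str] | None = None,
                 info: DesignInfo | None = None) -> tuple[np.ndarray, DesignInfo]:
    """Intercept + reference-coded design matrix for the given terms.

    Categorical (object/category) columns are expanded to indicator columns
    for every non-reference level; numeric columns enter as-is.  Passing a
    previously returned ``info`` re-applies the same encoding and raises on
    category levels not seen at fit time.
    """
    reference_levels = reference_levels or {}
    cols = [np.ones(len(df))]
    names = ["intercept"]
    levels: dict[str, list[str]] = {}
    refs: dict[str, str] = {}
    for term in terms:
        if term not in df.columns:
            raise KeyError(f"covariate {term!r} not present in data")
        col = df[term]
        if info is not None and term in info.levels:
            ref = info.reference[term]
            keep = info.levels[term]
            seen = set(col.astype(str).unique())
            unknown = seen - set(keep) - {ref}
            if unknown:
                raise ValueError(
                    f"covariate {term!r} has unseen categories: {sorted(unknown)}")
            for lev in keep:
                cols.append((col.astype(str) == lev).to_numpy(float))
                names.append(f"{term}[{lev}]")
            levels[term], refs[term] = keep, ref
        elif col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            cats = sorted(col.astype(str).unique())
            ref = reference_levels.get(term, cats[0])
            if ref not in cats:
                raise ValueError(
                    f"reference level {ref!r} not a category of {term!r}")
            keep = [c for c in cats if c != ref]
            for lev in keep:
                cols.append((col.astype(str) == lev).to_numpy(float))
                names.append(f"{term}[{lev}]")
            levels[term], refs[term] = keep, ref
        else:
            cols.append(col.to_numpy(float))
            names.append(term)
    x = np.column_stack(cols)
    return x, DesignInfo(terms=list(terms), columns=names, levels=levels,
                         reference=refs)


@dataclass
class DaleParameters:
    """Coefficient blocks of the three linear predictors."""

    beta1: np.ndarray
    beta2: np.ndarray
    beta3: np.ndarray

    def flatten(self) -> np.ndarray:
        return np.concatenate([self.beta1, self.beta2, self.beta3])

    @staticmethod
    def unflatten(theta: np.ndarray, k1: int, k2: int, k3: int) -> "DaleParameters":
        return DaleParameters(beta1=np.asarray(theta[:k1], float),
                              beta2=np.asarray(theta[k1:k1 + k2], float),
                              beta3=np.asarray(theta[k1 + k2:k1 + k2 + k3], float))


def linear_predictors(params: DaleParameters, x1: np.ndarray, x2: np.ndarray,
                      x3: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(eta1, eta2, eta3) = (X1 b1, X2 b2, X3 b3) for the three blocks."""
    return x1 @ params.beta1, x2 @ params.beta2, x3 @ params.beta3


def cell_probabilities(eta1, eta2, eta3):
    """Map linear predictors to the four joint cell probabilities.

    Returns an (n, 4) array in the order (p00, p01, p10, p11).
    """
    pi1 = _expit(eta1)
    pi2 = _expit(eta2)
    psi = np.exp(np.clip(eta3, -30, 30))
    p11 = plackett_p11(pi1, pi2, psi)
    p10 = pi1 - p11
    p01 = pi2 - p11
    p00 = 1.0 - pi1 - pi2 + p11
    return np.column_stack([p00, p01, p10, p11])


def cell_prob_and_grads(eta1, eta2, psi, cell):
    """Observed-cell probability and d log p_cell / d (eta1, eta2, eta3).

    Uses the closed-form Plackett derivatives; d p11 / d psi comes from
    implicit differentiation of p11 p00 = psi p10 p01 at fixed margins:
    d p11 / d psi = p10 p01 / (p00 + p11 + psi (p01 + p10)).
    """
    p1 = np.clip(1.0 / (1.0 + np.exp(-np.asarray(eta1, float))), 1e-12, 1 - 1e-12)
    p2 = np.clip(1.0 / (1.0 + np.exp(-np.asarray(eta2, float))), 1e-12, 1 - 1e-12)
    p11 = plackett_p11(p1, p2, psi)
    d1, d2 = plackett_dp11(p1, p2, psi)
    p10 = p1 - p11
    p01 = p2 - p11
    p00 = 1.0 - p1 - p2 + p11
    probs = np.column_stack([p00, p01, p10, p11])
    dp1 = np.column_stack([d1 - 1.0, -d1, 1.0 - d1, d1])
    dp2 = np.column_stack([d2 - 1.0, 1.0 - d2, -d2, d2])
    idx = np.arange(len(cell))
    pc = np.maximum(probs[idx, cell], _PROB_CLAMP)
    g1 = dp1[idx, cell] * p1 * (1 - p1) / pc
    g2 = dp2[idx, cell] * p2 * (1 - p2) / pc
    dpsi = p10 * p01 / np.maximum(p00 + p11 + psi * (p01 + p10), 1e-300)
    sign = np.where((cell == 0) | (cell == 3), 1.0, -1.0)
    g3 = sign * dpsi * psi / pc
    return pc, g1, g2, g3


def _expit(eta):
    # clipped to keep margins strictly interior for the Plackett solver
    out = 1.0 / (1.0 + np.exp(-np.asarray(eta, dtype=float)))
    return np.clip(out, 1e-12, 1.0 - 1e-12)


# ---------------------------------------------------------------------------
# Likelihood and fitting
# ---------------------------------------------------------------------------

class _Designs:
    """Precomputed design matrices, outcomes and weights for one dataset."""

    def __init__(self, data: pd.DataFrame, spec: ModelSpec,
                 infos: tuple[DesignInfo, DesignInfo, DesignInfo] | None = None):
        refs = spec.reference_levels
        i1, i2, i3 = infos if infos is not None else (None, None, None)
        self.x1, self.info1 = build_design(data, spec.formula1, refs, i1)
        self.x2, self.info2 = build_design(data, spec.formula2, refs, i2)
        self.x3, self.info3 = build_design(data, spec.formula3, refs, i3)
        self.y1 = data[spec.outcome1].to_numpy(int)
        self.y2 = data[spec.outcome2].to_numpy(int)
        if set(np.unique(self.y1)) - {0, 1} or set(np.unique(self.y2)) - {0, 1}:
            raise ValueError("outcomes must be coded 0/1")
        if spec.use_weights:
            self.w = data[spec.weight_col].to_numpy(float)
            if np.any(self.w <= 0):
                raise ValueError("survey weights must be positive")
        else:
            self.w = np.ones(len(data))
        self.cell = 2 * self.y1 + self.y2  # index into (p00,p01,p10,p11)

    @property
    def shape(self):
        return self.x1.shape[1], self.x2.shape[1], self.x3.shape[1]


def _loglik_arrays(params: DaleParameters, d: _Designs,
                   offset1: np.ndarray | float = 0.0,
                   offset2: np.ndarray | float = 0.0) -> float:
    eta1 = d.x1 @ params.beta1 + offset1
    eta2 = d.x2 @ params.beta2 + offset2
    eta3 = d.x3 @ params.beta3
    probs = cell_probabilities(eta1, eta2, eta3)
    p = probs[np.arange(len(d.cell)), d.cell]
    n_clamped = int(np.sum(p < _PROB_CLAMP))
    if n_clamped:
        logger.warning("clamped %d cell probabilities at %g", n_clamped, _PROB_CLAMP)
    return float(np.sum(d.w * np.log(np.maximum(p, _PROB_CLAMP))))


def loglik(params: DaleParameters, data: pd.DataFrame, spec: ModelSpec) -> float:
    """Weighted multinomial log-likelihood over the four joint cells."""
    return _loglik_arrays(params, _Designs(data, spec))


@dataclass
class DaleFit:
    """Maximum-likelihood fit of the bivariate binary logistic model."""

    params: DaleParameters
    vcov: np.ndarray
    loglik: float
    aic: float
    n_obs: int
    wald: pd.DataFrame
    converged: bool
    spec: ModelSpec
    designs: "_Designs"

    @property
    def n_params(self) -> int:
        return sum(self.designs.shape)

    def coefficient_table(self) -> pd.DataFrame:
        return self.wald.copy()


def _check_rank(x: np.ndarray, names: list[str], label: str) -> None:
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        # identify columns involved in the deficiency via QR pivoting
        _, r = np.linalg.qr(x)
        bad = [names[j] for j in range(x.shape[1]) if abs(r[j, j]) < 1e-8]
        raise np.linalg.LinAlgError(
            f"design for {label} is rank deficient (rank {rank} < {x.shape[1]}); "
            f"suspect columns: {bad}")


def numerical_hessian(f, theta: np.ndarray, rel_step: float = 1e-5) -> np.ndarray:
    """Central-difference Hessian with per-coordinate step 1e-5*(1+|theta_i|)."""
    k = len(theta)
    h = rel_step * (1.0 + np.abs(theta))
    hess = np.empty((k, k))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = h[i]
            ej = np.zeros(k); ej[j] = h[j]
            fpp = f(theta + ei + ej)
            fpm = f(theta + ei - ej)
            fmp = f(theta - ei + ej)
            fmm = f(theta - ei - ej)
            hess[i, j] = hess[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
    return hess


def wald_table(names: list[str], blocks: list[str], est: np.ndarray,
               vcov: np.ndarray) -> pd.DataFrame:
    se = np.sqrt(np.maximum(np.diag(vcov), 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, est / se, np.nan)
    p = 2 * stats.norm.sf(np.abs(z))
    return pd.DataFrame({"block": blocks, "term": names, "estimate": est,
                         "se": se, "z": z, "p": p})


def _default_start(d: _Designs) -> np.ndarray:
    k1, k2, k3 = d.shape
    m1 = np.clip(np.average(d.y1, weights=d.w), 0.01, 0.99)
    m2 = np.clip(np.average(d.y2, weights=d.w), 0.01, 0.99)
    n11 = np.sum(d.w * (d.cell == 3)); n10 = np.sum(d.w * (d.cell == 2))
    n01 = np.sum(d.w * (d.cell == 1)); n00 = np.sum(d.w * (d.cell == 0))
    if min(n11, n10, n01, n00) > 0:
        lpsi = np.log(n11 * n00 / (n10 * n01))
    else:
        lpsi = 0.0
    theta = np.zeros(k1 + k2 + k3)
    theta[0] = np.log(m1 / (1 - m1))
    theta[k1] = np.log(m2 / (1 - m2))
    theta[k1 + k2] = lpsi
    return theta


def fit_dale(data: pd.DataFrame, spec: ModelSpec,
             init: DaleParameters | None = None,
             gtol: float = 1e-8) -> DaleFit:
    """Maximum-likelihood fit of the Plackett/Dale model.

    Quasi-Newton (BFGS) on the negative weighted log-likelihood; the
    covariance of the estimates is the inverse observed information from a
    central-difference numerical Hessian.  Wald z and two-sided normal
    p-values are reported per coefficient.
    """
    for col in (spec.outcome1, spec.outcome2):
        vals = set(data[col].unique())
        if vals != {0, 1}:
            raise ValueError(f"outcome {col!r} must have both levels 0 and 1 "
                             f"present (saw {sorted(vals)})")
    d = _Designs(data, spec)
    k1, k2, k3 = d.shape
    _check_rank(d.x1, d.info1.columns, "outcome 1")
    _check_rank(d.x2, d.info2.columns, "outcome 2")
    _check_rank(d.x3, d.info3.columns, "association")

    theta0 = init.flatten() if init is not None else _default_start(d)

    def negll(theta):
        return -_loglik_arrays(DaleParameters.unflatten(theta, k1, k2, k3), d)

    def negll_grad(theta):
        p = DaleParameters.unflatten(theta, k1, k2, k3)
        eta1 = d.x1 @ p.beta1
        eta2 = d.x2 @ p.beta2
        psi = np.exp(np.clip(d.x3 @ p.beta3, -30, 30))
        pc, g1, g2, g3 = cell_prob_and_grads(eta1, eta2, psi, d.cell)
        nll = -float(np.sum(d.w * np.log(pc)))
        grad = -np.concatenate([d.x1.T @ (d.w * g1), d.x2.T @ (d.w * g2),
                                d.x3.T @ (d.w * g3)])
        return nll, grad

    res = optimize.minimize(negll_grad, theta0, jac=True, method="BFGS",
                            options={"gtol": gtol, "maxiter": 500})
    # BFGS can stop with "precision loss" at an already-excellent optimum;
    # accept when the gradient is tiny relative to the information scale
    converged = bool(res.success) or bool(np.max(np.abs(res.jac)) < 1e-4)
    if not converged:
        logger.warning("Dale fit did not converge: %s", res.message)
    theta = res.x
    params = DaleParameters.unflatten(theta, k1, k2, k3)
    ll = -res.fun
    k = k1 + k2 + k3
    hess = numerical_hessian(negll, theta)
    try:
        vcov = np.linalg.inv(hess)
    except np.linalg.LinAlgError:
        logger.warning("singular observed information; vcov set to NaN")
        vcov = np.full((k, k), np.nan)
        converged = False
    names = d.info1.columns + d.info2.columns + d.info3.columns
    blocks = (["outcome1"] * k1 + ["outcome2"] * k2 + ["association"] * k3)
    wald = wald_table(names, blocks, theta, vcov)
    return DaleFit(params=params, vcov=vcov, loglik=ll, aic=-2 * ll + 2 * k,
                   n_obs=len(data), wald=wald, converged=converged,
                   spec=spec, designs=d)


def fitted_cell_probabilities(fit: DaleFit, offset1=0.0, offset2=0.0) -> np.ndarray:
    d = fit.designs
    eta1 = d.x1 @ fit.params.beta1 + offset1
    eta2 = d.x2 @ fit.params.beta2 + offset2
    eta3 = d.x3 @ fit.params.beta3
    return cell_probabilities(eta1, eta2, eta3)
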