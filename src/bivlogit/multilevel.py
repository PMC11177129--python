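"""Bivariate binary multilevel (random-intercept) extension of the Dale model.

Each cluster j carries a bivariate normal random intercept (b1j, b2j) with
covariance Sigma added to the two marginal linear predictors; the cluster
contribution to the likelihood is the integral of the conditional Plackett
cell likelihood over the random effect, evaluated by two-dimensional
adaptive Gauss-Hermite quadrature standardized at the per-cluster posterior
mode and curvature.  The spatial auto-covariate S_i (neighbor-average zone
rate of each outcome) can enter the fixed part as a zone-level predictor.

Variance components are parameterized on a log-Cholesky scale during
optimization so that Sigma stays positive semidefinite; their standard
errors on the natural scale come from the delta method.  Note the usual
caveat: Wald p-values for variance components sit on the boundary of the
parameter space and are conservative at best.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import dale
from .dale import (DaleParameters, ModelSpec, _Designs, plackett_dp11,
                   wald_table, numerical_hessian)
from .simulate import ZoneGeometry
from . import spatial as sp

logger = logging.getLogger(__name__)

VARIANTS = ("random_intercept_L1", "random_intercept_L1L2",
            "random_intercept_crosslevel", "random_slope")


@dataclass
class RandomEffectCov:
    """Cluster random-intercept covariance: var1, var2 and their covariance."""

    var1: float
    var2: float
    cov12: float

    def matrix(self) -> np.ndarray:
        return np.array([[self.var1, self.cov12], [self.cov12, self.var2]])

    def __post_init__(self):
        if self.var1 < 0 or self.var2 < 0 or self.var1 * self.var2 - self.cov12 ** 2 < -1e-10:
            raise ValueError("random-effect covariance must be positive semidefinite")


@dataclass
class MultilevelSpec:
    base: ModelSpec
    cluster_key: str = "cluster_id"
    include_autocovariate: bool = False
    variant: str = "random_intercept_L1"
    quad_points: int = 7
    level2_terms: list[str] = field(default_factory=list)
    crosslevel_terms: list[tuple[str, str]] = field(default_factory=list)
    zone_key: str = "zone_id"

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.quad_points < 1:
            raise ValueError("quad_points must be >= 1")


@dataclass
class MultilevelFit:
    fixed: DaleParameters
    recov: RandomEffectCov
    loglik: float
    aic: float
    n_obs: int
    n_clusters: int
    converged: bool
    wald: pd.DataFrame
    vcov: np.ndarray | None
    spec: MultilevelSpec
    variant: str
    n_params: int
    data_fingerprint: str
    designs: "_Designs"
    cluster_order: np.ndarray
    modes: np.ndarray  # per-cluster posterior modes at the optimum


# ---------------------------------------------------------------------------
# Conditional likelihood machinery (vectorized over records and clusters)
# ---------------------------------------------------------------------------

def _cell_and_grad(eta1, eta2, psi, cell):
    """Per-record observed-cell probability and its d/d eta1, d/d eta2."""
    pc, g1, g2, _ = dale.cell_prob_and_grads(eta1, eta2, psi, cell)
    return pc, g1, g2


class _ClusterData:
    """Designs plus cluster bookkeeping for the marginal likelihood."""

    def __init__(self, data: pd.DataFrame, spec: ModelSpec, cluster_key: str):
        self.d = _Designs(data, spec)
        codes, self.cluster_order = pd.factorize(data[cluster_key], sort=True)
        self.cidx = codes
        self.n_clusters = len(self.cluster_order)

    def etas(self, params: DaleParameters):
        d = self.d
        return d.x1 @ params.beta1, d.x2 @ params.beta2, \
            np.exp(np.clip(d.x3 @ params.beta3, -30, 30))


def _cond_cluster_ll(cd: _ClusterData, eta1, eta2, psi, b):
    """Per-cluster weighted conditional log-likelihood at offsets b (J, 2)."""
    off1 = b[cd.cidx, 0]
    off2 = b[cd.cidx, 1]
    pc, _, _ = _cell_and_grad(eta1 + off1, eta2 + off2, psi, cd.d.cell)
    return np.bincount(cd.cidx, weights=cd.d.w * np.log(pc),
                       minlength=cd.n_clusters)


def _cond_cluster_grad(cd: _ClusterData, eta1, eta2, psi, b):
    """Per-cluster gradient (J, 2) of the conditional log-likelihood."""
    off1 = b[cd.cidx, 0]
    off2 = b[cd.cidx, 1]
    _, g1, g2 = _cell_and_grad(eta1 + off1, eta2 + off2, psi, cd.d.cell)
    out = np.empty((cd.n_clusters, 2))
    out[:, 0] = np.bincount(cd.cidx, weights=cd.d.w * g1, minlength=cd.n_clusters)
    out[:, 1] = np.bincount(cd.cidx, weights=cd.d.w * g2, minlength=cd.n_clusters)
    return out


def _find_modes(cd: _ClusterData, eta1, eta2, psi, prec: np.ndarray,
                b0: np.ndarray | None, tol: float = 1e-9,
                max_iter: int = 50) -> tuple[np.ndarray, np.ndarray]:
    """Posterior modes of (b1, b2) per cluster by damped Newton, vectorized.

    Returns (modes (J,2), neg_hessians (J,2,2)) where the Hessian is of the
    negative joint log-density (conditional + normal prior), estimated by
    central differences of the analytic gradient.
    """
    j = cd.n_clusters
    b = np.zeros((j, 2)) if b0 is None else b0.copy()

    def joint_val(bb):
        quad = 0.5 * np.einsum("ji,ik,jk->j", bb, prec, bb)
        return _cond_cluster_ll(cd, eta1, eta2, psi, bb) - quad

    def joint_grad(bb):
        return _cond_cluster_grad(cd, eta1, eta2, psi, bb) - bb @ prec.T

    val = joint_val(b)
    h = 1e-5
    for _ in range(max_iter):
        g = joint_grad(b)
        if np.max(np.abs(g)) < tol:
            break
        # FD Hessian of the conditional part, exact prior part
        e1 = np.zeros((j, 2)); e1[:, 0] = h
        e2 = np.zeros((j, 2)); e2[:, 1] = h
        c1 = (_cond_cluster_grad(cd, eta1, eta2, psi, b + e1)
              - _cond_cluster_grad(cd, eta1, eta2, psi, b - e1)) / (2 * h)
        c2 = (_cond_cluster_grad(cd, eta1, eta2, psi, b + e2)
              - _cond_cluster_grad(cd, eta1, eta2, psi, b - e2)) / (2 * h)
        hess = np.empty((j, 2, 2))
        hess[:, :, 0] = c1
        hess[:, :, 1] = c2
        hess[:, 0, 1] = hess[:, 1, 0] = 0.5 * (hess[:, 0, 1] + hess[:, 1, 0])
        neg_h = prec[None, :, :] - hess  # negative joint Hessian
        # ensure positive definiteness with a ridge
        det = neg_h[:, 0, 0] * neg_h[:, 1, 1] - neg_h[:, 0, 1] ** 2
        bad = (neg_h[:, 0, 0] <= 1e-10) | (det <= 1e-12)
        if np.any(bad):
            ridge = np.abs(neg_h[bad].diagonal(axis1=1, axis2=2)).max() + 1e-3
            neg_h[bad, 0, 0] += ridge
            neg_h[bad, 1, 1] += ridge
        det = neg_h[:, 0, 0] * neg_h[:, 1, 1] - neg_h[:, 0, 1] ** 2
        step = np.empty((j, 2))
        step[:, 0] = (neg_h[:, 1, 1] * g[:, 0] - neg_h[:, 0, 1] * g[:, 1]) / det
        step[:, 1] = (-neg_h[:, 1, 0] * g[:, 0] + neg_h[:, 0, 0] * g[:, 1]) / det
        # damped update (halve per-cluster until no decrease)
        alpha = np.ones(j)
        for _inner in range(20):
            cand = b + alpha[:, None] * step
            new_val = joint_val(cand)
            worse = new_val < val - 1e-12
            if not np.any(worse):
                break
            alpha[worse] *= 0.5
        b = b + alpha[:, None] * step
        val = joint_val(b)

    # final curvature at the mode
    e1 = np.zeros((j, 2)); e1[:, 0] = h
    e2 = np.zeros((j, 2)); e2[:, 1] = h
    c1 = (_cond_cluster_grad(cd, eta1, eta2, psi, b + e1)
          - _cond_cluster_grad(cd, eta1, eta2, psi, b - e1)) / (2 * h)
    c2 = (_cond_cluster_grad(cd, eta1, eta2, psi, b + e2)
          - _cond_cluster_grad(cd, eta1, eta2, psi, b - e2)) / (2 * h)
    hess = np.empty((j, 2, 2))
    hess[:, :, 0] = c1
    hess[:, :, 1] = c2
    hess[:, 0, 1] = hess[:, 1, 0] = 0.5 * (hess[:, 0, 1] + hess[:, 1, 0])
    neg_h = prec[None, :, :] - hess
    return b, neg_h


def _gh_nodes(q: int) -> tuple[np.ndarray, np.ndarray]:
    """2-D tensor-product Gauss-Hermite nodes (K, 2) and log-weights (K,)."""
    t, w = np.polynomial.hermite.hermgauss(q)
    t1, t2 = np.meshgrid(t, t)
    nodes = np.column_stack([t1.ravel(), t2.ravel()])
    logw = np.log(np.outer(w, w).ravel())
    return nodes, logw


def _marginal_loglik_clusters(cd: _ClusterData, params: DaleParameters,
                              sigma: np.ndarray, quad_points: int,
                              b_warm: np.ndarray | None = None
                              ) -> tuple[np.ndarray, np.ndarray]:
    """Per-cluster AGHQ marginal log-likelihood; returns (ll_j, modes)."""
    eta1, eta2, psi = cd.etas(params)
    if np.max(np.abs(sigma)) < 1e-12:
        ll = _cond_cluster_ll(cd, eta1, eta2, psi, np.zeros((cd.n_clusters, 2)))
        return ll, np.zeros((cd.n_clusters, 2))

    det_sig = sigma[0, 0] * sigma[1, 1] - sigma[0, 1] ** 2
    if det_sig <= 1e-14:
        # near-singular covariance: regularize minimally
        sigma = sigma + 1e-8 * np.eye(2)
        det_sig = sigma[0, 0] * sigma[1, 1] - sigma[0, 1] ** 2
    prec = np.array([[sigma[1, 1], -sigma[0, 1]],
                     [-sigma[0, 1], sigma[0, 0]]]) / det_sig

    modes, neg_h = _find_modes(cd, eta1, eta2, psi, prec, b_warm)

    # Cholesky of neg_h^{-1}, closed form per cluster
    det_h = neg_h[:, 0, 0] * neg_h[:, 1, 1] - neg_h[:, 0, 1] ** 2
    fallback = (det_h <= 1e-12) | (neg_h[:, 0, 0] <= 1e-12)
    if np.any(fallback):
        logger.warning("AGHQ curvature not PD for %d cluster(s); using prior "
                       "covariance scaling", int(np.sum(fallback)))
        neg_h[fallback] = prec[None, :, :]
        det_h = neg_h[:, 0, 0] * neg_h[:, 1, 1] - neg_h[:, 0, 1] ** 2
    inv = np.empty_like(neg_h)
    inv[:, 0, 0] = neg_h[:, 1, 1] / det_h
    inv[:, 1, 1] = neg_h[:, 0, 0] / det_h
    inv[:, 0, 1] = inv[:, 1, 0] = -neg_h[:, 0, 1] / det_h
    l11 = np.sqrt(inv[:, 0, 0])
    l21 = inv[:, 0, 1] / l11
    l22 = np.sqrt(np.maximum(inv[:, 1, 1] - l21 ** 2, 1e-300))
    log_det_c = np.log(l11) + np.log(l22)

    nodes, logw = _gh_nodes(quad_points)
    k = len(nodes)
    j = cd.n_clusters
    contrib = np.empty((k, j))
    log_norm = -np.log(2 * np.pi) - 0.5 * np.log(det_sig)
    sq2 = np.sqrt(2.0)
    for ki in range(k):
        t = nodes[ki]
        bk = np.empty((j, 2))
        bk[:, 0] = modes[:, 0] + sq2 * l11 * t[0]
        bk[:, 1] = modes[:, 1] + sq2 * (l21 * t[0] + l22 * t[1])
        cll = _cond_cluster_ll(cd, eta1, eta2, psi, bk)
        quad = 0.5 * np.einsum("ji,ik,jk->j", bk, prec, bk)
        g = cll - quad + log_norm
        contrib[ki] = logw[ki] + g + t @ t
    m = contrib.max(axis=0)
    ll = np.log(2.0) + log_det_c + m + np.log(np.sum(np.exp(contrib - m), axis=0))
    return ll, modes


def cluster_marginal_loglik(params: DaleParameters, recov: RandomEffectCov,
                            data: pd.DataFrame, spec: ModelSpec,
                            quad_points: int = 7,
                            cluster_key: str | None = None) -> float:
    """Marginal log-likelihood integrating the bivariate random intercept.

    If ``cluster_key`` is None all records are treated as a single cluster.
    """
    df = data.copy()
    key = cluster_key
    if key is None:
        key = "__cluster__"
        df[key] = 0
    cd = _ClusterData(df, spec, key)
    ll, _ = _marginal_loglik_clusters(cd, params, recov.matrix(), quad_points)
    return float(ll.sum())


# ---------------------------------------------------------------------------
# Variance-component parameterization (log-Cholesky)
# ---------------------------------------------------------------------------

def _sigma_from_lchol(phi: np.ndarray) -> np.ndarray:
    l11 = np.exp(phi[0])
    l21 = phi[1]
    l22 = np.exp(phi[2])
    return np.array([[l11 * l11, l11 * l21],
                     [l11 * l21, l21 * l21 + l22 * l22]])


def _lchol_jacobian(phi: np.ndarray) -> np.ndarray:
    """d(var1, var2, cov12) / d(phi) for the delta method."""
    l11, l21, l22 = np.exp(phi[0]), phi[1], np.exp(phi[2])
    return np.array([
        [2 * l11 * l11, 0.0, 0.0],                 # var1
        [0.0, 2 * l21, 2 * l22 * l22],             # var2
        [l11 * l21, l11, 0.0],                     # cov12
    ])


# ---------------------------------------------------------------------------
# Variant plumbing
# ---------------------------------------------------------------------------

def add_crosslevel_columns(data: pd.DataFrame,
                           pairs: list[tuple[str, str]],
                           reference_levels: dict[str, str] | None = None
                           ) -> tuple[pd.DataFrame, list[str]]:
    """Append product-indicator columns for each (level-1 x level-2) pair.

    Each non-reference level combination becomes one numeric 0/1 column
    named ``a[la]:b[lb]``; numeric covariates contribute themselves.
    """
    reference_levels = reference_levels or {}
    df = data.copy()
    names: list[str] = []

    def expand(col: str) -> list[tuple[str, np.ndarray]]:
        s = df[col]
        if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype):
            cats = sorted(s.astype(str).unique())
            ref = reference_levels.get(col, cats[0])
            return [(f"{col}[{c}]", (s.astype(str) == c).to_numpy(float))
                    for c in cats if c != ref]
        return [(col, s.to_numpy(float))]

    for a, b in pairs:
        for na, va in expand(a):
            for nb, vb in expand(b):
                name = f"{na}:{nb}"
                df[name] = va * vb
                names.append(name)
    return df, names


def attach_autocovariate(data: pd.DataFrame, zones: list[ZoneGeometry],
                         outcome1: str = "y1", outcome2: str = "y2",
                         weighted: bool = True, zone_key: str = "zone_id"
                         ) -> pd.DataFrame:
    """Merge per-outcome auto-covariate columns (neighbor-average zone rates).

    Adds ``autocov_<outcome>`` columns, constant within zone.
    """
    w = sp.build_weights(zones, style="binary")
    df = data.copy()
    for outcome in (outcome1, outcome2):
        rates = sp.zone_rates(data, outcome, weighted=weighted, zone_col=zone_key)
        si = sp.autocovariate(rates, w)
        gmean = float(np.mean(list(rates.rates.values())))
        df[f"autocov_{outcome}"] = df[zone_key].map(si).fillna(gmean)
    return df


def _effective_formulas(spec: MultilevelSpec, data: pd.DataFrame
                        ) -> tuple[pd.DataFrame, ModelSpec]:
    f1 = list(spec.base.formula1)
    f2 = list(spec.base.formula2)
    df = data
    if spec.variant in ("random_intercept_L1L2", "random_intercept_crosslevel"):
        f1 += [t for t in spec.level2_terms if t not in f1]
        f2 += [t for t in spec.level2_terms if t not in f2]
    if spec.variant == "random_intercept_crosslevel":
        pairs = spec.crosslevel_terms
        if not pairs:
            raise ValueError("crosslevel variant requires crosslevel_terms")
        df, inter = add_crosslevel_columns(df, pairs, spec.base.reference_levels)
        f1 += inter
        f2 += inter
    if spec.include_autocovariate:
        for col in (f"autocov_{spec.base.outcome1}", f"autocov_{spec.base.outcome2}"):
            if col not in df.columns:
                raise ValueError(
                    f"auto-covariate column {col!r} missing: call "
                    "attach_autocovariate (or pass zones to fit_multilevel)")
        f1.append(f"autocov_{spec.base.outcome1}")
        f2.append(f"autocov_{spec.base.outcome2}")
    eff = ModelSpec(formula1=f1, formula2=f2, formula3=list(spec.base.formula3),
                    reference_levels=spec.base.reference_levels,
                    use_weights=spec.base.use_weights,
                    outcome1=spec.base.outcome1, outcome2=spec.base.outcome2,
                    weight_col=spec.base.weight_col)
    return df, eff


def _fingerprint(data: pd.DataFrame, spec: MultilevelSpec) -> str:
    h = hashlib.sha256()
    h.update(data[spec.base.outcome1].to_numpy(int).tobytes())
    h.update(data[spec.base.outcome2].to_numpy(int).tobytes())
    h.update(str(len(data)).encode())
    return h.hexdigest()[:16]


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def fit_multilevel(data: pd.DataFrame, spec: MultilevelSpec,
                   zones: list[ZoneGeometry] | None = None,
                   compute_se: bool = True, force: bool = False,
                   maxiter: int = 200) -> MultilevelFit:
    """Maximum-likelihood fit of the bivariate random-intercept model.

    Optimizes fixed effects jointly with log-Cholesky variance components
    over the AGHQ marginal likelihood.  The auto-covariate, when requested,
    is computed from ``zones`` and enters each outcome's fixed part as a
    zone-level predictor.
    """
    if spec.variant == "random_slope" and not force:
        raise NotImplementedError(
            "random_slope variant not estimated: reported lack of convergence; "
            "pass force=True to attempt anyway")
    fingerprint = _fingerprint(data, spec)
    df = data
    if spec.include_autocovariate and not any(
            c.startswith("autocov_") for c in df.columns):
        if zones is None:
            raise ValueError("include_autocovariate requires zone geometry")
        df = attach_autocovariate(df, zones, spec.base.outcome1,
                                  spec.base.outcome2,
                                  weighted=spec.base.use_weights,
                                  zone_key=spec.zone_key)
    df, eff_spec = _effective_formulas(spec, df)
    cd = _ClusterData(df, eff_spec, spec.cluster_key)
    if cd.n_clusters < 2:
        raise ValueError("need at least 2 clusters")
    k1, k2, k3 = cd.d.shape
    kf = k1 + k2 + k3

    # warm start: single-level fit for the fixed part
    start_fit = dale.fit_dale(df, eff_spec, gtol=1e-5)
    phi0 = np.array([np.log(0.45), 0.05, np.log(0.45)])
    theta0 = np.concatenate([start_fit.params.flatten(), phi0])

    warm = {"b": None}

    def negll(theta):
        params = DaleParameters.unflatten(theta[:kf], k1, k2, k3)
        sigma = _sigma_from_lchol(theta[kf:])
        ll, modes = _marginal_loglik_clusters(cd, params, sigma,
                                              spec.quad_points, warm["b"])
        warm["b"] = modes
        return -float(ll.sum())

    from scipy import optimize
    res = optimize.minimize(negll, theta0, method="L-BFGS-B",
                            options={"maxiter": maxiter, "ftol": 1e-11,
                                     "gtol": 1e-6, "eps": 1e-5})
    converged = bool(res.success)
    if not converged:
        logger.warning("multilevel fit did not converge: %s", res.message)
    theta = res.x
    ll = -float(res.fun)
    params = DaleParameters.unflatten(theta[:kf], k1, k2, k3)
    sigma = _sigma_from_lchol(theta[kf:])
    recov = RandomEffectCov(var1=float(sigma[0, 0]), var2=float(sigma[1, 1]),
                            cov12=float(sigma[0, 1]))
    k_total = kf + 3
    aic = -2 * ll + 2 * k_total

    names = (cd.d.info1.columns + cd.d.info2.columns + cd.d.info3.columns)
    blocks = ["outcome1"] * k1 + ["outcome2"] * k2 + ["association"] * k3
    vc_names = ["var(intercept_1)", "var(intercept_2)", "cov(intercept_1,intercept_2)"]
    vc_est = np.array([recov.var1, recov.var2, recov.cov12])

    vcov = None
    if compute_se:
        hess = numerical_hessian(negll, theta, rel_step=3e-4)
        try:
            vcov = np.linalg.inv(hess)
        except np.linalg.LinAlgError:
            logger.warning("singular observed information in multilevel fit")
            vcov = np.full((len(theta), len(theta)), np.nan)
        fixed_tab = wald_table(names, blocks, theta[:kf], vcov[:kf, :kf])
        jac = _lchol_jacobian(theta[kf:])
        vc_cov = jac @ vcov[kf:, kf:] @ jac.T
        vc_tab = wald_table(vc_names, ["variance"] * 3, vc_est, vc_cov)
        logger.info("variance-component Wald p-values are boundary tests; "
                    "interpret conservatively")
        wald = pd.concat([fixed_tab, vc_tab], ignore_index=True)
    else:
        nan = np.full(kf + 3, np.nan)
        wald = pd.DataFrame({"block": blocks + ["variance"] * 3,
                             "term": names + vc_names,
                             "estimate": np.concatenate([theta[:kf], vc_est]),
                             "se": nan, "z": nan, "p": nan})

    # final modes for diagnostics / empirical Bayes
    _, modes = _marginal_loglik_clusters(cd, params, sigma, spec.quad_points,
                                         warm["b"])
    return MultilevelFit(fixed=params, recov=recov, loglik=ll, aic=aic,
                         n_obs=len(df), n_clusters=cd.n_clusters,
                         converged=converged, wald=wald, vcov=vcov, spec=spec,
                         variant=spec.variant, n_params=k_total,
                         data_fingerprint=fingerprint, designs=cd.d,
                         cluster_order=np.asarray(cd.cluster_order),
                         modes=modes)


def empirical_bayes_intercepts(fit: MultilevelFit) -> dict:
    """Posterior modes of the cluster random intercepts at the estimates.

    Modes shrink toward (0, 0) as cluster information vanishes and as the
    random-effect covariance shrinks to zero.
    """
    return {c: (float(b1), float(b2))
            for c, (b1, b2) in zip(fit.cluster_order, fit.modes)}


def compare_models(fits: list[MultilevelFit]) -> pd.DataFrame:
    """Rank fits by AIC (ascending); ties broken by fewer parameters;
    non-converged fits ranked last and flagged."""
    if not fits:
        raise ValueError("no fits to compare")
    prints = {f.data_fingerprint for f in fits}
    if len(prints) > 1:
        raise ValueError("fits were not computed on identical data")
    rows = [{"variant": f.variant, "loglik": f.loglik, "k": f.n_params,
             "aic": f.aic, "converged": f.converged} for f in fits]
    tab = pd.DataFrame(rows)
    tab = tab.sort_values(by=["converged", "aic", "k"],
                          ascending=[False, True, True]).reset_index(drop=True)
    tab["rank"] = np.arange(1, len(tab) + 1)
    return tab
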