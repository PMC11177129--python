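"""Zone-level spatial statistics: weights, auto-covariate, Moran's I,
Getis-Ord Gi*, Local Moran (LISA), and ordinary kriging of area rates.

Conventions: Moran's I and Local Moran use row-standardized weights; Gi*
uses binary weights with self-inclusion.  Island zones (no neighbors) are
excluded from the autocorrelation statistics with a warning, and their
auto-covariate value falls back to the global mean rate.  Coordinates are
treated as planar.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .simulate import ZoneGeometry, adjacency_matrix

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Weights and rates
# ---------------------------------------------------------------------------

@dataclass
class SpatialWeights:
    """Zone neighbor structure as a dense matrix (zero diagonal)."""

    zone_order: list[int]
    w: np.ndarray
    style: str  # binary | row_standardized

    def index_of(self, zone_id) -> int:
        return self.zone_order.index(zone_id)


def build_weights(zones: list[ZoneGeometry], style: str = "binary") -> SpatialWeights:
    """Contiguity weights in the requested style.

    Islands produce all-zero rows (logged).  Asymmetric adjacency raises.
    """
    if style not in ("binary", "row_standardized"):
        raise ValueError(f"unknown weight style {style!r}")
    a = adjacency_matrix(zones)  # raises on asymmetry
    islands = np.where(a.sum(axis=1) == 0)[0]
    if len(islands):
        logger.warning("weights contain %d island zone(s): %s", len(islands),
                       [zones[i].zone_id for i in islands])
    if style == "row_standardized":
        rs = a.sum(axis=1, keepdims=True)
        a = np.divide(a, rs, out=np.zeros_like(a), where=rs > 0)
    return SpatialWeights(zone_order=[z.zone_id for z in zones], w=a, style=style)


@dataclass
class ZoneRates:
    """Per-zone outcome proportion with its (possibly weighted) denominator."""

    rates: dict[int, float] = field(default_factory=dict)
    denominators: dict[int, float] = field(default_factory=dict)

    def aligned(self, zone_order: list[int]) -> np.ndarray:
        return np.array([self.rates[z] for z in zone_order])


def zone_rates(data: pd.DataFrame, outcome: str, weighted: bool = True,
               weight_col: str = "weight", zone_col: str = "zone_id") -> ZoneRates:
    """Survey-weighted (or unweighted) outcome proportion per zone."""
    w = data[weight_col].to_numpy(float) if weighted else np.ones(len(data))
    y = data[outcome].to_numpy(float)
    z = data[zone_col].to_numpy()
    out = ZoneRates()
    for zid in pd.unique(z):
        m = z == zid
        tot = w[m].sum()
        if tot <= 0:
            logger.warning("zone %s excluded: zero total weight", zid)
            continue
        out.rates[int(zid)] = float(np.sum(w[m] * y[m]) / tot)
        out.denominators[int(zid)] = float(tot)
    return out


def autocovariate(rates: ZoneRates, weights: SpatialWeights) -> dict[int, float]:
    """Neighbor-average rate S_i = sum_j w_ij y_j / sum_j w_ij (w_ii = 0).

    Island zones get the global mean rate.
    """
    if not rates.rates:
        raise ValueError("empty zone rates")
    order = [z for z in weights.zone_order if z in rates.rates]
    idx = [weights.zone_order.index(z) for z in order]
    w = weights.w[np.ix_(idx, idx)]
    y = np.array([rates.rates[z] for z in order])
    num = w @ y
    den = w.sum(axis=1)
    gmean = float(np.mean(y))
    si = np.where(den > 0, num / np.where(den > 0, den, 1.0), gmean)
    return {z: float(s) for z, s in zip(order, si)}


def _nonisland(rates: ZoneRates, weights: SpatialWeights):
    """Aligned rate vector and weight submatrix over non-island zones with data."""
    order = [z for z in weights.zone_order if z in rates.rates]
    idx = [weights.zone_order.index(z) for z in order]
    w = weights.w[np.ix_(idx, idx)]
    deg = w.sum(axis=1)
    keep = deg > 0
    if not np.all(keep):
        logger.warning("excluding %d island zone(s) from autocorrelation",
                       int(np.sum(~keep)))
        order = [z for z, k in zip(order, keep) if k]
        w = w[np.ix_(np.where(keep)[0], np.where(keep)[0])]
    y = np.array([rates.rates[z] for z in order])
    return order, y, w


# ---------------------------------------------------------------------------
# Global Moran's I
# ---------------------------------------------------------------------------

@dataclass
class MoranResult:
    i: float
    expected_i: float
    z: float
    p_analytic: float
    p_perm: float
    n: int
    n_perm: int


def _moran_stat(y: np.ndarray, w: np.ndarray) -> float:
    d = y - y.mean()
    s0 = w.sum()
    return float(len(y) / s0 * (d @ w @ d) / (d @ d))


def global_morans_i(rates: ZoneRates, weights: SpatialWeights,
                    n_perm: int = 999, seed: int = 0) -> MoranResult:
    """Global Moran's I with analytic (randomization) and permutation p-values.

    I = (n / S0) * sum_ij w_ij (y_i - ybar)(y_j - ybar) / sum_i (y_i - ybar)^2;
    E[I] = -1/(n-1) under spatial randomness.
    """
    _, y, w = _nonisland(rates, weights)
    n = len(y)
    if n < 3:
        raise ValueError("need at least 3 zones")
    d = y - y.mean()
    if np.allclose(d, 0):
        raise ValueError("zero variance in zone rates")
    i_obs = _moran_stat(y, w)
    e_i = -1.0 / (n - 1)

    # randomization variance (standard S0/S1/S2/b2 formula)
    s0 = w.sum()
    s1 = 0.5 * np.sum((w + w.T) ** 2)
    s2 = np.sum((w.sum(axis=1) + w.sum(axis=0)) ** 2)
    b2 = n * np.sum(d ** 4) / (np.sum(d ** 2) ** 2)
    num = n * ((n * n - 3 * n + 3) * s1 - n * s2 + 3 * s0 * s0) \
        - b2 * ((n * n - n) * s1 - 2 * n * s2 + 6 * s0 * s0)
    var_i = num / ((n - 1) * (n - 2) * (n - 3) * s0 * s0) - e_i ** 2
    z = (i_obs - e_i) / np.sqrt(var_i)
    p_analytic = 2 * stats.norm.sf(abs(z))

    # one-sided (positive autocorrelation) permutation pseudo p
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        if _moran_stat(rng.permutation(y), w) >= i_obs:
            count += 1
    p_perm = (count + 1) / (n_perm + 1)
    return MoranResult(i=i_obs, expected_i=e_i, z=float(z),
                       p_analytic=float(p_analytic), p_perm=float(p_perm),
                       n=n, n_perm=n_perm)


# ---------------------------------------------------------------------------
# Local statistics
# ---------------------------------------------------------------------------

@dataclass
class LocalStatResult:
    zone_order: list[int]
    statistic: np.ndarray
    z: np.ndarray
    p: np.ndarray
    category: list[str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"zone_id": self.zone_order, "statistic": self.statistic,
                             "z": self.z, "p": self.p, "category": self.category})


def local_gi_star(rates: ZoneRates, weights: SpatialWeights) -> LocalStatResult:
    """Getis-Ord Gi* hot/cold-spot z-scores with self-included binary weights.

    z_i = [sum_j w_ij y_j - ybar W_i] / (s sqrt[(n S1i - W_i^2)/(n-1)])
    with w_ii = 1 added, W_i = sum_j w_ij, S1i = sum_j w_ij^2, and ybar, s
    over all n zones.  Categories bin |z| at 1.645 / 1.960 / 2.576.
    """
    if weights.style != "binary":
        raise ValueError("Gi* requires binary weights")
    order, y, w = _nonisland(rates, weights)
    n = len(y)
    if n < 3:
        raise ValueError("need at least 3 zones")
    if np.allclose(y, y.mean()):
        raise ValueError("zero variance in zone rates")
    ws = w + np.eye(n)  # self-inclusion
    ybar = y.mean()
    s = np.sqrt(np.sum(y * y) / n - ybar * ybar)
    wi = ws.sum(axis=1)
    s1i = np.sum(ws * ws, axis=1)
    num = ws @ y - ybar * wi
    # a zone whose neighborhood (incl. self) spans all n zones has zero
    # denominator: its Gi* is undefined (NaN)
    with np.errstate(invalid="ignore", divide="ignore"):
        den = s * np.sqrt((n * s1i - wi * wi) / (n - 1))
        z = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
        p = 2 * stats.norm.sf(np.abs(z))
    cats = []
    for zi in z:
        if np.isnan(zi):
            cats.append("undefined")
        elif zi >= 2.576:
            cats.append("hotspot99")
        elif zi >= 1.960:
            cats.append("hotspot95")
        elif zi >= 1.645:
            cats.append("hotspot90")
        elif zi <= -2.576:
            cats.append("coldspot99")
        elif zi <= -1.960:
            cats.append("coldspot95")
        elif zi <= -1.645:
            cats.append("coldspot90")
        else:
            cats.append("not-significant")
    return LocalStatResult(zone_order=order, statistic=z.copy(), z=z, p=p,
                           category=cats)


def local_moran(rates: ZoneRates, weights: SpatialWeights,
                n_perm: int = 999, seed: int = 0,
                alpha: float = 0.05) -> LocalStatResult:
    """Local Moran I_i with conditional-permutation pseudo p-values.

    I_i = z_i * sum_j w_ij z_j on standardized rates (sample sd); zones are
    typed HH/LL (clusters) or HL/LH (outliers) from the signs of z_i and its
    spatial lag, NS when the pseudo p exceeds ``alpha``.
    """
    if weights.style != "row_standardized":
        raise ValueError("Local Moran requires row-standardized weights")
    order, y, w = _nonisland(rates, weights)
    n = len(y)
    if n < 3:
        raise ValueError("need at least 3 zones")
    d = y - y.mean()
    if np.allclose(d, 0):
        raise ValueError("zero variance in zone rates")
    zstd = d / y.std(ddof=1)
    lag = w @ zstd
    i_local = zstd * lag

    rng = np.random.default_rng(seed)
    p = np.empty(n)
    for i in range(n):
        others = np.delete(zstd, i)
        wrow = np.delete(w[i], i)
        nz = wrow > 0
        k = int(nz.sum())
        if k == 0:
            p[i] = 1.0
            continue
        wnz = wrow[nz]
        # draw k neighbors without replacement from the other n-1 values
        picks = np.empty((n_perm, k))
        for b in range(n_perm):
            picks[b] = others[rng.choice(n - 1, size=k, replace=False)]
        sims = zstd[i] * (picks @ wnz)
        extreme = np.sum(sims >= i_local[i]) if i_local[i] >= 0 \
            else np.sum(sims <= i_local[i])
        p[i] = (extreme + 1) / (n_perm + 1)

    cats = []
    for i in range(n):
        if p[i] >= alpha:
            cats.append("NS")
        elif zstd[i] > 0 and lag[i] > 0:
            cats.append("HH")
        elif zstd[i] < 0 and lag[i] < 0:
            cats.append("LL")
        elif zstd[i] > 0:
            cats.append("HL")
        else:
            cats.append("LH")
    return LocalStatResult(zone_order=order, statistic=i_local,
                           z=zstd, p=p, category=cats)


# ---------------------------------------------------------------------------
# Ordinary kriging
# ---------------------------------------------------------------------------

@dataclass
class VariogramModel:
    """Exponential semivariogram gamma(h) = nugget + sill (1 - exp(-h/range))."""

    nugget: float
    sill: float
    range_: float

    def __call__(self, h):
        h = np.asarray(h, dtype=float)
        g = self.nugget + self.sill * (1.0 - np.exp(-h / max(self.range_, 1e-12)))
        return np.where(h == 0, 0.0, g)


@dataclass
class KrigingResult:
    grid_x: np.ndarray
    grid_y: np.ndarray
    prediction: np.ndarray
    variance: np.ndarray
    variogram: VariogramModel
    empirical: pd.DataFrame  # columns: lag, gamma, n_pairs
    weights: np.ndarray | None = None  # (n_nodes, n_zones) kriging weights

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"x": self.grid_x, "y": self.grid_y,
                             "prediction": self.prediction,
                             "kriging_variance": self.variance})


def empirical_semivariogram(coords: np.ndarray, values: np.ndarray,
                            n_bins: int = 10) -> pd.DataFrame:
    diff = coords[:, None, :] - coords[None, :, :]
    h = np.sqrt((diff ** 2).sum(-1))
    gv = 0.5 * (values[:, None] - values[None, :]) ** 2
    iu = np.triu_indices(len(values), k=1)
    h, gv = h[iu], gv[iu]
    edges = np.linspace(0, h.max() * (1 + 1e-9), n_bins + 1)
    rows = []
    for b in range(n_bins):
        m = (h >= edges[b]) & (h < edges[b + 1])
        if m.sum() == 0:
            continue
        rows.append((h[m].mean(), gv[m].mean(), int(m.sum())))
    return pd.DataFrame(rows, columns=["lag", "gamma", "n_pairs"])


def fit_variogram(emp: pd.DataFrame) -> VariogramModel:
    """Weighted least squares (pair counts / gamma^2, Cressie) exponential fit;
    negative nugget clamped to zero with a warning."""
    lags = emp["lag"].to_numpy()
    gam = emp["gamma"].to_numpy()
    npairs = emp["n_pairs"].to_numpy(float)

    def resid(theta):
        nug, sill, rng_ = theta
        model = nug + sill * (1.0 - np.exp(-lags / max(rng_, 1e-9)))
        wts = np.sqrt(npairs) / np.maximum(model, 1e-9)
        return wts * (gam - model)

    g0 = max(gam.max(), 1e-6)
    x0 = np.array([0.0, g0, max(lags.max() / 3.0, 1e-6)])
    res = optimize.least_squares(resid, x0, bounds=([0, 1e-12, 1e-9],
                                                    [np.inf, np.inf, np.inf]))
    nug, sill, rng_ = res.x
    if nug < 0:
        logger.warning("negative fitted nugget %.3g clamped to 0", nug)
        nug = 0.0
    return VariogramModel(nugget=float(nug), sill=float(sill), range_=float(rng_))


def krige_rates(rates: ZoneRates, zones: list[ZoneGeometry],
                grid: tuple[np.ndarray, np.ndarray] | None = None,
                n_grid: int = 20, n_bins: int = 10,
                variogram: VariogramModel | None = None) -> KrigingResult:
    """Ordinary kriging of zone rates onto a planar grid.

    Solves the standard constrained system per node; weights sum to 1.
    With a zero nugget, predictions at observed centroids interpolate the
    data exactly.
    """
    order = [z.zone_id for z in zones if z.zone_id in rates.rates]
    coords = np.array([z.centroid for z in zones if z.zone_id in rates.rates])
    vals = np.array([rates.rates[z] for z in order])
    n = len(vals)
    if n < 5 and variogram is None:
        # the kriging system itself works for any n >= 2, but estimating a
        # semivariogram from fewer than 5 sites is meaningless
        raise ValueError("need at least 5 zones to estimate a variogram; "
                         "pass an explicit variogram model for fewer")
    if n < 2:
        raise ValueError("need at least 2 zones with rates")
    d = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt((d ** 2).sum(-1))
    if np.any(dist[np.triu_indices(n, k=1)] == 0):
        raise ValueError("duplicate centroids make the kriging system singular")

    emp = empirical_semivariogram(coords, vals, n_bins=n_bins)
    vg = variogram if variogram is not None else fit_variogram(emp)
    if vg.nugget == 0 and vg.sill <= 1e-12:
        # flat (constant-rate) field: every unbiased predictor returns the
        # constant; avoid a numerically singular system
        vg = VariogramModel(nugget=0.0, sill=1e-10, range_=max(vg.range_, 1.0))

    if grid is None:
        gx = np.linspace(coords[:, 0].min(), coords[:, 0].max(), n_grid)
        gy = np.linspace(coords[:, 1].min(), coords[:, 1].max(), n_grid)
        gx, gy = [g.ravel() for g in np.meshgrid(gx, gy)]
    else:
        gx, gy = np.asarray(grid[0], float).ravel(), np.asarray(grid[1], float).ravel()

    a = np.empty((n + 1, n + 1))
    a[:n, :n] = vg(dist)
    a[n, :n] = 1.0
    a[:n, n] = 1.0
    a[n, n] = 0.0
    try:
        a_inv = np.linalg.inv(a)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular kriging matrix") from exc

    pts = np.column_stack([gx, gy])
    d0 = np.sqrt(((coords[None, :, :] - pts[:, None, :]) ** 2).sum(-1))
    rhs = np.empty((len(pts), n + 1))
    rhs[:, :n] = vg(d0)
    rhs[:, n] = 1.0
    lam = rhs @ a_inv.T
    pred = lam[:, :n] @ vals
    var = np.sum(lam * rhs, axis=1)
    return KrigingResult(grid_x=gx, grid_y=gy, prediction=pred,
                         variance=np.maximum(var, 0.0), variogram=vg,
                         empirical=emp, weights=lam[:, :n])
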