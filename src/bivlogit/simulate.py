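"""Synthetic three-level survey generator with known ground truth.

Emulates the structure of a DHS-style sample of women nested in clusters
nested in administrative zones: correlated bivariate binary outcomes built
from marginal logits plus a constant odds ratio (Plackett construction),
bivariate-normal cluster random intercepts, spatially autocorrelated
zone-level shifts on a planar lattice with rook contiguity, categorical
covariates at woman/cluster/zone level, and unequal sampling weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .dale import plackett_p11


@dataclass(frozen=True)
class ZoneGeometry:
    """One zone on the lattice: planar centroid plus symmetric neighbor set."""

    zone_id: int
    centroid: tuple[float, float]
    neighbors: tuple[int, ...]


@dataclass
class CovariateSpec:
    """One categorical covariate: name, labels, category probabilities.

    ``labels[0]`` is the reference category; ``level`` controls whether the
    draw is per woman, constant within cluster, or constant within zone.
    """

    name: str
    labels: list[str]
    probs: list[float]
    level: str = "woman"  # woman | cluster | zone

    def __post_init__(self):
        if abs(sum(self.probs) - 1.0) > 1e-12:
            raise ValueError(f"category probabilities of {self.name!r} must sum to 1")
        if len(self.labels) != len(self.probs):
            raise ValueError("labels and probs must have equal length")
        if self.level not in ("woman", "cluster", "zone"):
            raise ValueError(f"unknown covariate level {self.level!r}")


@dataclass
class SimulationConfig:
    n_zones: int = 74
    lattice_dims: tuple[int, int] = (9, 9)
    clusters_per_zone: int = 9
    women_per_cluster: int = 5
    # coefficient order: intercept, then non-reference dummies of each
    # covariate in covariate_spec order (labels[1:], in order)
    beta1: np.ndarray = field(default_factory=lambda: np.array([0.0]))
    beta2: np.ndarray = field(default_factory=lambda: np.array([0.0]))
    log_psi: float = 0.0
    re_cov: np.ndarray = field(default_factory=lambda: np.zeros((2, 2)))
    zone_sd: float = 0.0
    zone_rho: float = 0.0
    zone_effects_shared: bool = True
    weight_range: tuple[float, float] = (0.5, 2.0)
    informative_weights: bool = False
    covariate_spec: list[CovariateSpec] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self):
        self.beta1 = np.atleast_1d(np.asarray(self.beta1, float))
        self.beta2 = np.atleast_1d(np.asarray(self.beta2, float))
        self.re_cov = np.asarray(self.re_cov, float)
        if self.lattice_dims[0] * self.lattice_dims[1] < self.n_zones:
            raise ValueError("lattice too small for n_zones")
        if not (0.0 <= self.zone_rho < 1.0):
            raise ValueError("zone_rho must lie in [0, 1)")
        if self.zone_sd < 0:
            raise ValueError("zone_sd must be nonnegative")
        if self.re_cov.shape != (2, 2) or abs(self.re_cov[0, 1] - self.re_cov[1, 0]) > 1e-12:
            raise ValueError("re_cov must be a symmetric 2x2 matrix")
        if np.min(np.linalg.eigvalsh(self.re_cov)) < -1e-10:
            raise ValueError("re_cov must be positive semidefinite")
        if self.weight_range[0] <= 0 or self.weight_range[1] < self.weight_range[0]:
            raise ValueError("weight_range must be positive and ordered")
        k = 1 + sum(len(c.labels) - 1 for c in self.covariate_spec)
        if len(self.beta1) != k or len(self.beta2) != k:
            raise ValueError(
                f"beta vectors must have length {k} (intercept + dummies), "
                f"got {len(self.beta1)} and {len(self.beta2)}")


def default_config(seed: int = 0) -> SimulationConfig:
    """Study-scale default scenario: 74 zones, 9 clusters each, 5 women per
    cluster (~3300 women), baseline prevalences near 0.58 and 0.75, outcome
    odds ratio 1.4, cluster random-intercept covariance (0.39, 0.52, 0.07),
    moderate spatial zone effects, and rural/wealth/media covariates."""
    covs = [
        CovariateSpec("residence", ["urban", "rural"], [0.31, 0.69], level="cluster"),
        CovariateSpec("wealth", ["richest", "poorest", "poorer", "middle", "richer"],
                      [0.30, 0.12, 0.16, 0.20, 0.22]),
        CovariateSpec("media", ["yes", "no"], [0.62, 0.38]),
    ]
    # order: intercept, residence[rural], wealth[poorest..richer], media[no]
    beta1 = np.array([-0.40, 0.49, 0.53, 0.61, 0.45, 0.53, 0.10])
    beta2 = np.array([0.55, 0.16, 0.20, 0.07, 0.13, 0.04, 0.03])
    return SimulationConfig(
        n_zones=74, lattice_dims=(9, 9), clusters_per_zone=9, women_per_cluster=5,
        beta1=beta1, beta2=beta2, log_psi=float(np.log(1.4)),
        re_cov=np.array([[0.393, 0.071], [0.071, 0.518]]),
        zone_sd=0.35, zone_rho=0.8, weight_range=(0.5, 2.0),
        covariate_spec=covs, seed=seed)


# ---------------------------------------------------------------------------
# Geometry and zone effects
# ---------------------------------------------------------------------------

def make_zone_lattice(config: SimulationConfig) -> list[ZoneGeometry]:
    """Place zones row-major on a regular grid with rook (edge) adjacency."""
    nr, nc = config.lattice_dims
    n = config.n_zones
    if nr * nc < n:
        raise ValueError("lattice too small for n_zones")
    zones = []
    for z in range(n):
        r, c = divmod(z, nc)
        nb = []
        for rr, cc in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)):
            if 0 <= rr < nr and 0 <= cc < nc:
                j = rr * nc + cc
                if j < n:
                    nb.append(j)
        zones.append(ZoneGeometry(zone_id=z, centroid=(float(c), float(r)),
                                  neighbors=tuple(sorted(nb))))
    return zones


def adjacency_matrix(zones: list[ZoneGeometry]) -> np.ndarray:
    order = {z.zone_id: i for i, z in enumerate(zones)}
    a = np.zeros((len(zones), len(zones)))
    for z in zones:
        for j in z.neighbors:
            a[order[z.zone_id], order[j]] = 1.0
    if not np.allclose(a, a.T):
        raise ValueError("neighbor relation must be symmetric")
    return a


def simulate_zone_effects(zones: list[ZoneGeometry], config: SimulationConfig,
                          rng: np.random.Generator | None = None) -> dict[int, float]:
    """Spatially autocorrelated zone shifts from a proper CAR-style scheme.

    Effect vector = zone_sd * L z with z iid standard normal and L the
    Cholesky factor of (D - rho A)^(-1) rescaled to unit average diagonal,
    so zone_sd is the average marginal standard deviation regardless of rho.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n = len(zones)
    if config.zone_sd == 0.0:
        rng.standard_normal(n)  # keep the stream position deterministic
        return {z.zone_id: 0.0 for z in zones}
    a = adjacency_matrix(zones)
    deg = a.sum(axis=1)
    prec = np.diag(np.maximum(deg, 1.0)) - config.zone_rho * a
    try:
        cov = np.linalg.inv(prec)
    except np.linalg.LinAlgError as exc:
        raise ValueError("zone precision matrix is singular: zone_rho too close "
                         "to 1 for this adjacency graph") from exc
    if np.min(np.linalg.eigvalsh(prec)) <= 1e-10:
        raise ValueError("zone precision matrix is not positive definite")
    cov = cov / np.mean(np.diag(cov))
    chol = np.linalg.cholesky(cov)
    eff = config.zone_sd * (chol @ rng.standard_normal(n))
    return {z.zone_id: float(e) for z, e in zip(zones, eff)}


# ---------------------------------------------------------------------------
# Dataset simulation
# ---------------------------------------------------------------------------

def _draw_categories(rng, spec: CovariateSpec, n: int) -> np.ndarray:
    idx = rng.choice(len(spec.labels), size=n, p=spec.probs)
    return np.array(spec.labels, dtype=object)[idx]


def simulate_dataset(config: SimulationConfig):
    """Generate (records DataFrame, zones, truth dict) under the config.

    Per cluster, a bivariate-normal random intercept (b1, b2); per woman,
    covariates, a sampling weight, and one of the four outcome cells drawn
    from the Plackett joint probabilities at eta1 = x'b1 + b1j + zone
    effect, eta2 likewise, psi = exp(log_psi).  Fully reproducible for a
    given seed.
    """
    rng = np.random.default_rng(config.seed)
    zones = make_zone_lattice(config)
    eff1 = simulate_zone_effects(zones, config, rng)
    if config.zone_effects_shared:
        eff2 = eff1
    else:
        eff2 = simulate_zone_effects(zones, config, rng)

    n_clusters = config.n_zones * config.clusters_per_zone
    n_women = n_clusters * config.women_per_cluster

    # cluster random intercepts
    if np.all(config.re_cov == 0):
        b = np.zeros((n_clusters, 2))
        rng.standard_normal((n_clusters, 2))
    else:
        chol = np.linalg.cholesky(config.re_cov + 1e-12 * np.eye(2))
        b = rng.standard_normal((n_clusters, 2)) @ chol.T

    zone_of_cluster = np.repeat([z.zone_id for z in zones], config.clusters_per_zone)
    cluster_of_woman = np.repeat(np.arange(n_clusters), config.women_per_cluster)
    zone_of_woman = zone_of_cluster[cluster_of_woman]

    # covariates at their level, broadcast down to women
    cov_cols: dict[str, np.ndarray] = {}
    for cs in config.covariate_spec:
        if cs.level == "woman":
            cov_cols[cs.name] = _draw_categories(rng, cs, n_women)
        elif cs.level == "cluster":
            vals = _draw_categories(rng, cs, n_clusters)
            cov_cols[cs.name] = vals[cluster_of_woman]
        else:
            vals = _draw_categories(rng, cs, config.n_zones)
            cov_cols[cs.name] = vals[zone_of_woman]

    # design matrix in config coefficient order
    x = [np.ones(n_women)]
    for cs in config.covariate_spec:
        col = cov_cols[cs.name]
        for lab in cs.labels[1:]:
            x.append((col == lab).astype(float))
    x = np.column_stack(x)

    ze1 = np.array([eff1[z] for z in zone_of_woman])
    ze2 = np.array([eff2[z] for z in zone_of_woman])
    eta1 = x @ config.beta1 + b[cluster_of_woman, 0] + ze1
    eta2 = x @ config.beta2 + b[cluster_of_woman, 1] + ze2
    pi1 = 1.0 / (1.0 + np.exp(-eta1))
    pi2 = 1.0 / (1.0 + np.exp(-eta2))
    pi1 = np.clip(pi1, 1e-12, 1 - 1e-12)
    pi2 = np.clip(pi2, 1e-12, 1 - 1e-12)
    p11 = plackett_p11(pi1, pi2, np.exp(config.log_psi))
    p10 = pi1 - p11
    p01 = pi2 - p11
    p00 = 1.0 - pi1 - pi2 + p11
    cum = np.cumsum(np.column_stack([p00, p01, p10, p11]), axis=1)
    u = rng.uniform(size=n_women)
    cell = (u[:, None] > cum).sum(axis=1)  # 0..3 -> (00,01,10,11)
    y1 = (cell >= 2).astype(int)
    y2 = (cell % 2).astype(int)

    lo, hi = config.weight_range
    w = rng.uniform(lo, hi, size=n_women)
    if config.informative_weights:
        # tie weights to the zone effect (monotone rescale inside the range)
        rank = (ze1 - ze1.min()) / (np.ptp(ze1) + 1e-12)
        w = lo + (hi - lo) * (0.5 * rank + 0.5 * (w - lo) / (hi - lo))

    records = pd.DataFrame({
        "woman_id": np.arange(n_women),
        "zone_id": zone_of_woman,
        "cluster_id": cluster_of_woman,
        "y1": y1,
        "y2": y2,
        **cov_cols,
        "weight": w,
    })
    truth = {
        "beta1": config.beta1.tolist(),
        "beta2": config.beta2.tolist(),
        "log_psi": config.log_psi,
        "psi": float(np.exp(config.log_psi)),
        "re_cov": config.re_cov.tolist(),
        "zone_sd": config.zone_sd,
        "zone_rho": config.zone_rho,
        "zone_effects_y1": {int(k): v for k, v in eff1.items()},
        "zone_effects_y2": {int(k): v for k, v in eff2.items()},
        "cluster_intercepts": b.tolist(),
        "coefficient_names": ["intercept"] + [
            f"{cs.name}[{lab}]" for cs in config.covariate_spec for lab in cs.labels[1:]],
        "seed": config.seed,
    }
    return records, zones, truth


# ---------------------------------------------------------------------------
# Text I/O
# ---------------------------------------------------------------------------

def write_records_csv(records: pd.DataFrame, path) -> None:
    records.to_csv(path, index=False)


def write_zones_csv(zones: list[ZoneGeometry], path) -> None:
    pd.DataFrame({"zone_id": [z.zone_id for z in zones],
                  "x": [z.centroid[0] for z in zones],
                  "y": [z.centroid[1] for z in zones]}).to_csv(path, index=False)


def write_edges_csv(zones: list[ZoneGeometry], path) -> None:
    rows = [(z.zone_id, j) for z in zones for j in z.neighbors if z.zone_id < j]
    pd.DataFrame(rows, columns=["zone_a", "zone_b"]).to_csv(path, index=False)


def write_truth_yaml(truth: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(truth, fh, sort_keys=False)


def read_zones_csv(zones_path, edges_path) -> list[ZoneGeometry]:
    zdf = pd.read_csv(zones_path)
    edf = pd.read_csv(edges_path)
    nb: dict[int, set[int]] = {int(z): set() for z in zdf["zone_id"]}
    for a, b_ in zip(edf["zone_a"], edf["zone_b"]):
        nb[int(a)].add(int(b_))
        nb[int(b_)].add(int(a))
    return [ZoneGeometry(zone_id=int(r.zone_id), centroid=(float(r.x), float(r.y)),
                         neighbors=tuple(sorted(nb[int(r.zone_id)])))
            for r in zdf.itertuples()]
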