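"""End-to-end orchestration: simulate-or-load, weighted descriptives,
zone-level spatial statistics, the random-intercept model ladder, residual
diagnostics, and an exponentiated odds-ratio report.

Every stage writes plain CSV into the output directory and the run manifest
records the seed, a config hash, package versions and stage timings, so a
rerun with the same config and seed is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import descriptives as desc
from . import multilevel as ml
from . import simulate as sim
from . import spatial as sp
from .dale import ModelSpec
from .multilevel import MultilevelFit, MultilevelSpec

logger = logging.getLogger(__name__)

STAGES = ("simulate", "describe", "spatial", "fit", "report")


@dataclass
class PipelineConfig:
    """Exactly one of (records/zones/edges paths) or (simulation) must be set."""

    seed: int
    out_dir: str
    records_path: str | None = None
    zones_path: str | None = None
    edges_path: str | None = None
    simulation: sim.SimulationConfig | None = None
    outcome1: str = "y1"
    outcome2: str = "y2"
    weight_col: str = "weight"
    zone_col: str = "zone_id"
    cluster_col: str = "cluster_id"
    predictors_l1: list[str] = field(default_factory=list)
    predictors_l2: list[str] = field(default_factory=list)
    crosslevel_terms: list[tuple[str, str]] = field(default_factory=list)
    reference_levels: dict[str, str] = field(default_factory=dict)
    use_weights: bool = True
    variants: list[str] = field(default_factory=lambda: [
        "random_intercept_L1", "random_intercept_L1L2"])
    include_autocovariate: bool = True
    quad_points: int = 7
    n_perm: int = 999
    drop_unlocated_zone_records: bool = True

    def __post_init__(self):
        has_paths = self.records_path is not None
        has_sim = self.simulation is not None
        if has_paths == has_sim:
            raise ValueError(
                "exactly one of input paths or a simulation config is required")
        if has_paths and (self.zones_path is None or self.edges_path is None):
            raise ValueError("records_path requires zones_path and edges_path")
        if self.seed is None:
            raise ValueError("seed is required")

    def config_hash(self) -> str:
        d = dataclasses.asdict(self)
        if self.simulation is not None:
            d["simulation"]["beta1"] = list(map(float, self.simulation.beta1))
            d["simulation"]["beta2"] = list(map(float, self.simulation.beta2))
            d["simulation"]["re_cov"] = np.asarray(self.simulation.re_cov).tolist()
        blob = yaml.safe_dump(d, sort_keys=True, default_flow_style=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def config_from_yaml(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    simcfg = None
    if "simulation" in raw and raw["simulation"] is not None:
        s = dict(raw.pop("simulation"))
        covs = [sim.CovariateSpec(**c) for c in s.pop("covariate_spec", [])]
        for key in ("beta1", "beta2"):
            if key in s:
                s[key] = np.asarray(s[key], float)
        if "re_cov" in s:
            s["re_cov"] = np.asarray(s["re_cov"], float)
        for key in ("lattice_dims", "weight_range"):
            if key in s:
                s[key] = tuple(s[key])
        simcfg = sim.SimulationConfig(covariate_spec=covs, **s)
    raw["crosslevel_terms"] = [tuple(t) for t in raw.get("crosslevel_terms", [])]
    return PipelineConfig(simulation=simcfg, **raw)


# ---------------------------------------------------------------------------
# Diagnostics
# ---------------------------------------------------------------------------

@dataclass
class DiagnosticsReport:
    residuals: pd.DataFrame        # columns: outcome, residual, fitted
    summary: pd.DataFrame          # per-outcome mean/sd/skew/quantiles
    linearity: pd.DataFrame        # residual means across fitted deciles

    def passed_counts(self) -> int:
        return len(self.residuals)


def pearson_residual(y, pihat):
    """(y - pihat) / sqrt(pihat (1 - pihat)), elementwise."""
    y = np.asarray(y, float)
    pihat = np.asarray(pihat, float)
    return (y - pihat) / np.sqrt(pihat * (1.0 - pihat))


def pearson_residuals(fit: MultilevelFit, data: pd.DataFrame) -> DiagnosticsReport:
    """Pearson residuals of both outcomes at the fitted marginal
    probabilities, including the empirical-Bayes cluster intercepts.

    r = (y - pihat) / sqrt(pihat (1 - pihat)); residuals whose fitted
    probability sits at the clamp boundary are flagged.
    """
    if not fit.converged:
        raise ValueError("diagnostics require a converged fit")
    d = fit.designs
    eb = ml.empirical_bayes_intercepts(fit)
    b = np.array([eb[c] for c in data[fit.spec.cluster_key]])
    eta1 = d.x1 @ fit.fixed.beta1 + b[:, 0]
    eta2 = d.x2 @ fit.fixed.beta2 + b[:, 1]
    rows = []
    for outcome, eta, y in (("outcome1", eta1, d.y1), ("outcome2", eta2, d.y2)):
        pi = np.clip(1.0 / (1.0 + np.exp(-eta)), 1e-12, 1 - 1e-12)
        r = pearson_residual(y, pi)
        flagged = (pi <= 1e-12) | (pi >= 1 - 1e-12)
        rows.append(pd.DataFrame({"outcome": outcome, "residual": r,
                                  "fitted": pi, "flagged": flagged}))
    res = pd.concat(rows, ignore_index=True)

    qs = [0.01, 0.05, 0.25, 0.5, 0.75, 0.95, 0.99]
    summ = []
    for outcome, grp in res.groupby("outcome"):
        r = grp["residual"]
        row = {"outcome": outcome, "mean": r.mean(), "sd": r.std(ddof=1),
               "skew": float(r.skew())}
        for q in qs:
            row[f"q{int(q * 100):02d}"] = float(r.quantile(q))
        summ.append(row)

    lin = []
    for outcome, grp in res.groupby("outcome"):
        dec = pd.qcut(grp["fitted"].rank(method="first"), 10, labels=False)
        for dc, sub in grp.groupby(dec):
            lin.append({"outcome": outcome, "decile": int(dc) + 1,
                        "mean_fitted": sub["fitted"].mean(),
                        "mean_residual": sub["residual"].mean(),
                        "n": len(sub)})
    return DiagnosticsReport(residuals=res, summary=pd.DataFrame(summ),
                             linearity=pd.DataFrame(lin))


def odds_ratio_report(fit: MultilevelFit) -> pd.DataFrame:
    """exp(estimate) with 95% Wald intervals per coefficient block."""
    if not fit.converged:
        raise ValueError("odds-ratio report requires a converged fit")
    tab = fit.wald[fit.wald["block"] != "variance"].copy()
    tab["odds_ratio"] = np.round(np.exp(tab["estimate"]), 2)
    tab["or_low"] = np.round(np.exp(tab["estimate"] - 1.96 * tab["se"]), 2)
    tab["or_high"] = np.round(np.exp(tab["estimate"] + 1.96 * tab["se"]), 2)
    return tab[["block", "term", "estimate", "se", "p",
                "odds_ratio", "or_low", "or_high"]]


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.10g")


def run_pipeline(config: PipelineConfig,
                 stages: tuple[str, ...] = STAGES) -> dict:
    """Execute the requested stages in order; returns the artifact bundle.

    Stage outputs are written as CSV under ``config.out_dir``; a failure
    halts with the stage name while earlier outputs remain on disk.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict = {"out_dir": str(out)}
    timings: dict[str, float] = {}
    stage = "setup"
    try:
        t0 = time.perf_counter()
        stage = "simulate"
        if config.simulation is not None:
            records, zones, truth = sim.simulate_dataset(config.simulation)
            if "simulate" in stages:
                sim.write_records_csv(records, out / "records.csv")
                sim.write_zones_csv(zones, out / "zones.csv")
                sim.write_edges_csv(zones, out / "edges.csv")
                sim.write_truth_yaml(truth, out / "truth.yaml")
            bundle["truth"] = truth
        else:
            records = pd.read_csv(config.records_path)
            zones = sim.read_zones_csv(config.zones_path, config.edges_path)

        # exclusions, logged with record-count deltas
        n0 = len(records)
        records = records.dropna(subset=[config.outcome1, config.outcome2])
        if len(records) != n0:
            logger.info("dropped %d records with missing outcomes", n0 - len(records))
        located = {z.zone_id for z in zones
                   if np.isfinite(z.centroid[0]) and np.isfinite(z.centroid[1])}
        zones = [z for z in zones if z.zone_id in located]
        if config.drop_unlocated_zone_records:
            n1 = len(records)
            records = records[records[config.zone_col].isin(located)]
            if len(records) != n1:
                logger.info("dropped %d records in unlocated zones", n1 - len(records))
        bundle["records"] = records
        bundle["zones"] = zones
        timings["simulate"] = time.perf_counter() - t0

        if "describe" in stages:
            stage = "describe"
            t0 = time.perf_counter()
            jp, tab = desc.joint_marginal_summary(
                records, config.outcome1, config.outcome2,
                weighted=config.use_weights, weight_col=config.weight_col)
            table2 = pd.DataFrame({
                "quantity": ["p11", "p10", "p01", "p00", "margin1", "margin2",
                             "odds_ratio"],
                "value": [round(jp.p11, 3), round(jp.p10, 3), round(jp.p01, 3),
                          round(jp.p00, 3), round(jp.pi1, 3), round(jp.pi2, 3),
                          round(jp.psi, 3)]})
            _write(table2, out / "table2_joint_marginal.csv")
            preds = config.predictors_l1 + config.predictors_l2
            tests = desc.chisq_screen(records, preds, config.outcome1,
                                      config.outcome2, weighted=config.use_weights,
                                      weight_col=config.weight_col)
            screen = pd.DataFrame([{"predictor": t.predictor,
                                    "chi_square": round(t.statistic, 3),
                                    "df": t.df, "p": round(t.p, 4),
                                    "warning": t.warning or ""} for t in tests])
            _write(screen, out / "table1_chisq_screen.csv")
            bundle["table2"] = jp
            bundle["chisq"] = tests
            bundle["prevalence"] = {
                config.outcome1: desc.prevalence(records, config.outcome1,
                                                 config.use_weights, config.weight_col),
                config.outcome2: desc.prevalence(records, config.outcome2,
                                                 config.use_weights, config.weight_col),
            }
            timings["describe"] = time.perf_counter() - t0

        if "spatial" in stages:
            stage = "spatial"
            t0 = time.perf_counter()
            wb = sp.build_weights(zones, "binary")
            wr = sp.build_weights(zones, "row_standardized")
            rows = []
            spatial_res = {}
            for outcome in (config.outcome1, config.outcome2):
                rates = sp.zone_rates(records, outcome, config.use_weights,
                                      config.weight_col, config.zone_col)
                si = sp.autocovariate(rates, wb)
                moran = sp.global_morans_i(rates, wr, config.n_perm, config.seed)
                gi = sp.local_gi_star(rates, wb)
                lisa = sp.local_moran(rates, wr, config.n_perm, config.seed)
                krig = sp.krige_rates(rates, zones)
                _write(krig.to_frame(),
                       out / f"kriging_surface_{outcome}.csv")
                gi_f = gi.to_frame().set_index("zone_id")
                li_f = lisa.to_frame().set_index("zone_id")
                for z in gi_f.index:
                    rows.append({
                        "outcome": outcome, "zone_id": z,
                        "rate": round(rates.rates[z], 4),
                        "autocovariate": round(si[z], 4),
                        "gi_z": round(gi_f.loc[z, "z"], 4),
                        "gi_category": gi_f.loc[z, "category"],
                        "lisa_i": round(li_f.loc[z, "statistic"], 4),
                        "lisa_p": round(li_f.loc[z, "p"], 4),
                        "lisa_category": li_f.loc[z, "category"]})
                spatial_res[outcome] = {"rates": rates, "moran": moran,
                                        "gi": gi, "lisa": lisa, "kriging": krig,
                                        "autocovariate": si}
            _write(pd.DataFrame(rows), out / "spatial_zone_stats.csv")
            moran_tab = pd.DataFrame(
                [{"outcome": oc, "morans_i": round(r["moran"].i, 4),
                  "expected_i": round(r["moran"].expected_i, 4),
                  "z": round(r["moran"].z, 4),
                  "p_analytic": round(r["moran"].p_analytic, 6),
                  "p_perm": round(r["moran"].p_perm, 6)}
                 for oc, r in spatial_res.items()])
            _write(moran_tab, out / "global_moran.csv")
            bundle["spatial"] = spatial_res
            timings["spatial"] = time.perf_counter() - t0

        if "fit" in stages:
            stage = "fit"
            t0 = time.perf_counter()
            base = ModelSpec(formula1=list(config.predictors_l1),
                             formula2=list(config.predictors_l1),
                             reference_levels=config.reference_levels,
                             use_weights=config.use_weights,
                             outcome1=config.outcome1, outcome2=config.outcome2,
                             weight_col=config.weight_col)
            fits = []
            for variant in config.variants:
                mspec = MultilevelSpec(
                    base=base, cluster_key=config.cluster_col,
                    include_autocovariate=config.include_autocovariate,
                    variant=variant, quad_points=config.quad_points,
                    level2_terms=list(config.predictors_l2),
                    crosslevel_terms=list(config.crosslevel_terms),
                    zone_key=config.zone_col)
                try:
                    fits.append(ml.fit_multilevel(records, mspec, zones))
                except NotImplementedError as exc:
                    logger.warning("variant %s skipped: %s", variant, exc)
            if not fits:
                raise RuntimeError("no model variant could be fitted")
            comparison = ml.compare_models(fits)
            _write(comparison, out / "model_comparison.csv")
            for f in fits:
                _write(f.wald.round(6), out / f"coefficients_{f.variant}.csv")
            best_variant = comparison[comparison["converged"]].iloc[0]["variant"]
            best = next(f for f in fits if f.variant == best_variant)
            bundle["fits"] = fits
            bundle["comparison"] = comparison
            bundle["best_fit"] = best
            timings["fit"] = time.perf_counter() - t0

        if "report" in stages and "best_fit" in bundle:
            stage = "report"
            t0 = time.perf_counter()
            best = bundle["best_fit"]
            orr = odds_ratio_report(best)
            _write(orr.round(6), out / "odds_ratio_report.csv")
            diag = pearson_residuals(best, records)
            _write(diag.summary.round(6), out / "residual_summary.csv")
            _write(diag.linearity.round(6), out / "residual_linearity.csv")
            bundle["odds_ratios"] = orr
            bundle["diagnostics"] = diag
            timings["report"] = time.perf_counter() - t0

        manifest = {
            "package": "bivlogit", "version": __version__,
            "numpy": np.__version__, "pandas": pd.__version__,
            "seed": config.seed, "config_hash": config.config_hash(),
            "stages": list(stages), "timings_s": {k: round(v, 3)
                                                  for k, v in timings.items()},
            "n_records": int(len(records)), "n_zones": len(zones),
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        bundle["manifest"] = manifest
        return bundle
    except Exception:
        logger.error("pipeline halted in stage %r; partial outputs in %s",
                     stage, out)
        raise
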