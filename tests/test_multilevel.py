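"""Marginal likelihood (AGHQ), multilevel fitting, model comparison."""

import numpy as np
import pandas as pd
import pytest

import _oracles as orc
from bivlogit.dale import DaleParameters, ModelSpec, loglik
from bivlogit import multilevel as ml
from bivlogit.multilevel import (MultilevelFit, MultilevelSpec, RandomEffectCov,
                                 cluster_marginal_loglik, compare_models,
                                 empirical_bayes_intercepts, fit_multilevel)
from bivlogit.simulate import CovariateSpec, SimulationConfig, simulate_dataset


PARAMS = DaleParameters(beta1=np.array([0.3]), beta2=np.array([-0.2]),
                        beta3=np.array([float(np.log(2))]))


def _tiny_cluster(seed=0, n=2):
    rng = np.random.default_rng(seed)
    return pd.DataFrame({"y1": rng.integers(0, 2, n),
                         "y2": rng.integers(0, 2, n),
                         "cluster_id": 0, "weight": 1.0})


class TestClusterMarginalLoglik:
    def test_degenerate_covariance_equals_single_level(self):
        df = _tiny_cluster(1, 6)
        recov = RandomEffectCov(0.0, 0.0, 0.0)
        ll = cluster_marginal_loglik(PARAMS, recov, df, ModelSpec(), quad_points=7)
        assert ll == pytest.approx(loglik(PARAMS, df, ModelSpec()), abs=1e-10)

    def test_matches_brute_force_grid(self):
        df = pd.DataFrame({"y1": [1, 0], "y2": [1, 1],
                           "cluster_id": 0, "weight": 1.0})
        sigma = np.array([[1.0, 0.5], [0.5, 1.0]])
        recov = RandomEffectCov(1.0, 1.0, 0.5)
        ll = cluster_marginal_loglik(PARAMS, recov, df, ModelSpec(), quad_points=15)
        cells = (2 * df.y1 + df.y2).to_numpy()
        ref = orc.brute_force_cluster_loglik(
            np.full(2, 0.3), np.full(2, -0.2), 2.0, cells, sigma)
        assert ll == pytest.approx(ref, abs=1e-6)

    def test_quadrature_refinement_converges(self):
        df = _tiny_cluster(3, 8)
        recov = RandomEffectCov(0.8, 0.6, 0.2)
        vals = [cluster_marginal_loglik(PARAMS, recov, df, ModelSpec(),
                                        quad_points=q) for q in (3, 7, 15)]
        assert abs(vals[1] - vals[2]) <= abs(vals[0] - vals[2]) + 1e-12

    def test_weighted_conditional_contributions(self):
        df = _tiny_cluster(5, 4).assign(weight=2.0)
        spec_w = ModelSpec(use_weights=True)
        recov = RandomEffectCov(0.0, 0.0, 0.0)
        ll_w = cluster_marginal_loglik(PARAMS, recov, df, spec_w)
        ll_u = cluster_marginal_loglik(PARAMS, recov, df.assign(weight=1.0),
                                       spec_w)
        assert ll_w == pytest.approx(2 * ll_u, rel=1e-12)


def _sim(seed, n_zones=24, cpz=5, wpc=20, zone_sd=0.0, level2=False,
         re_cov=None, log_psi=float(np.log(1.4))):
    covs = [CovariateSpec("xvar", ["a", "b"], [0.5, 0.5])]
    beta1 = [-0.4, 0.5]
    beta2 = [0.4, -0.5]
    if level2:
        covs.append(CovariateSpec("res", ["u", "r"], [0.4, 0.6], level="cluster"))
        beta1 = beta1 + [0.8]
        beta2 = beta2 + [0.6]
    cfg = SimulationConfig(
        n_zones=n_zones, lattice_dims=(6, max(4, -(-n_zones // 6))),
        clusters_per_zone=cpz, women_per_cluster=wpc,
        beta1=np.array(beta1), beta2=np.array(beta2), log_psi=log_psi,
        re_cov=np.array(re_cov) if re_cov is not None
        else np.array([[0.4, 0.07], [0.07, 0.5]]),
        zone_sd=zone_sd, zone_rho=0.8, covariate_spec=covs, seed=seed)
    return simulate_dataset(cfg)


BASE = ModelSpec(formula1=["xvar"], formula2=["xvar"])


class TestFitMultilevel:
    def test_parameter_recovery_single_replicate(self):
        rec, zones, truth = _sim(101, n_zones=30, cpz=5, wpc=25)
        spec = MultilevelSpec(base=BASE, quad_points=7)
        fit = fit_multilevel(rec, spec)
        assert fit.converged
        est = fit.wald.set_index("term")
        for term, true_val in [("xvar[b]", 0.5)]:
            row = est.loc[term].iloc[0]
            assert abs(row["estimate"] - true_val) < 3 * row["se"]
        assert abs(fit.recov.var1 - 0.4) < 3 * est.loc["var(intercept_1)"]["se"]
        assert abs(fit.recov.var2 - 0.5) < 3 * est.loc["var(intercept_2)"]["se"]

    def test_aic_counts_parameters(self):
        rec, zones, _ = _sim(7, n_zones=12, cpz=3, wpc=10)
        fit = fit_multilevel(rec, MultilevelSpec(base=BASE, quad_points=5),
                             compute_se=False)
        k = 2 + 2 + 1 + 3  # two marginal blocks, log-OR intercept, 3 var comps
        assert fit.n_params == k
        assert fit.aic == pytest.approx(-2 * fit.loglik + 2 * k, abs=1e-9)

    def test_loglik_invariant_to_cluster_relabeling(self):
        rec, _, _ = _sim(8, n_zones=12, cpz=3, wpc=10)
        fit1 = fit_multilevel(rec, MultilevelSpec(base=BASE, quad_points=5),
                              compute_se=False)
        relabeled = rec.assign(cluster_id=997 - rec.cluster_id)
        fit2 = fit_multilevel(relabeled, MultilevelSpec(base=BASE, quad_points=5),
                              compute_se=False)
        assert fit1.loglik == pytest.approx(fit2.loglik, abs=1e-4)

    def test_random_slope_stub(self):
        rec, _, _ = _sim(9, n_zones=12, cpz=3, wpc=5)
        spec = MultilevelSpec(base=BASE, variant="random_slope")
        with pytest.raises(NotImplementedError, match="lack of convergence"):
            fit_multilevel(rec, spec)

    def test_autocovariate_needs_zones(self):
        rec, _, _ = _sim(10, n_zones=12, cpz=3, wpc=5)
        spec = MultilevelSpec(base=BASE, include_autocovariate=True)
        with pytest.raises(ValueError, match="zone"):
            fit_multilevel(rec, spec, zones=None)

    def test_level2_predictors_lower_aic(self):
        """Adding level-2 covariates that truly matter improves AIC."""
        rec, zones, _ = _sim(11, n_zones=24, cpz=4, wpc=15, level2=True)
        l1 = fit_multilevel(rec, MultilevelSpec(
            base=BASE, variant="random_intercept_L1", quad_points=5),
            compute_se=False)
        l1l2 = fit_multilevel(rec, MultilevelSpec(
            base=BASE, variant="random_intercept_L1L2", quad_points=5,
            level2_terms=["res"]), compute_se=False)
        assert l1l2.aic < l1.aic

    def test_autocovariate_columns_attached(self):
        rec, zones, _ = _sim(12, n_zones=12, cpz=3, wpc=10, zone_sd=0.5)
        df = ml.attach_autocovariate(rec, zones)
        assert {"autocov_y1", "autocov_y2"} <= set(df.columns)
        assert (df.groupby("zone_id")["autocov_y1"].nunique() == 1).all()


class TestEmpiricalBayes:
    def test_modes_shrink_with_vanishing_variance(self):
        rec, _, _ = _sim(13, n_zones=12, cpz=3, wpc=10, re_cov=[[0.4, 0.0], [0.0, 0.4]])
        spec = MultilevelSpec(base=BASE, quad_points=5)
        fit = fit_multilevel(rec, spec, compute_se=False)
        cd = ml._ClusterData(rec, ml._effective_formulas(spec, rec)[1],
                             spec.cluster_key)
        _, modes_small = ml._marginal_loglik_clusters(
            cd, fit.fixed, 1e-8 * np.eye(2), 5)
        assert np.max(np.abs(modes_small)) < 1e-3

    def test_all_ones_cluster_has_positive_mode(self):
        df = pd.DataFrame({
            "y1": [1] * 40 + [0, 1] * 20,
            "y2": [0, 1] * 40,
            "cluster_id": [0] * 40 + [1] * 40,
            "weight": 1.0})
        recov = RandomEffectCov(1.0, 1.0, 0.0)
        params = DaleParameters(beta1=np.array([0.0]), beta2=np.array([0.0]),
                                beta3=np.array([0.0]))
        cd = ml._ClusterData(df, ModelSpec(), "cluster_id")
        _, modes = ml._marginal_loglik_clusters(cd, params, recov.matrix(), 7)
        assert modes[0, 0] > 0.3     # all-ones cluster pulled up
        # brute-force posterior-mode check on a grid
        g = np.linspace(-3, 3, 601)
        from bivlogit.dale import cell_probabilities
        best = max(g, key=lambda b: 40 * np.log(
            cell_probabilities(np.array([b]), np.array([0.0]),
                               np.array([0.0]))[0, 2:].sum()) - 0.5 * b * b)
        assert modes[0, 0] == pytest.approx(best, abs=0.02)


def _dummy_fit(variant, aic, k=5, converged=True, fingerprint="f"):
    return MultilevelFit(
        fixed=PARAMS, recov=RandomEffectCov(0.1, 0.1, 0.0),
        loglik=-(aic - 2 * k) / 2, aic=aic, n_obs=10, n_clusters=2,
        converged=converged, wald=pd.DataFrame(), vcov=None,
        spec=None, variant=variant, n_params=k, data_fingerprint=fingerprint,
        designs=None, cluster_order=np.array([0, 1]), modes=np.zeros((2, 2)))


class TestCompareModels:
    def test_smallest_aic_wins(self):
        tab = compare_models([_dummy_fit("a", 6228.3), _dummy_fit("b", 6208.3),
                              _dummy_fit("c", 6301.3)])
        assert tab.iloc[0]["variant"] == "b"

    def test_single_fit(self):
        tab = compare_models([_dummy_fit("only", 100.0)])
        assert list(tab["variant"]) == ["only"]

    def test_tie_broken_by_fewer_parameters(self):
        tab = compare_models([_dummy_fit("big", 50.0, k=7),
                              _dummy_fit("small", 50.0, k=5)])
        assert tab.iloc[0]["variant"] == "small"

    def test_nonconverged_ranked_last(self):
        tab = compare_models([_dummy_fit("bad", 10.0, converged=False),
                              _dummy_fit("ok", 99.0)])
        assert tab.iloc[0]["variant"] == "ok"

    def test_mismatched_data_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            compare_models([_dummy_fit("a", 1.0, fingerprint="x"),
                            _dummy_fit("b", 2.0, fingerprint="y")])
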