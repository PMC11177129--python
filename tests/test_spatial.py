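"""Spatial weights, auto-covariate, Moran/Gi*/LISA against naive oracles,
and ordinary kriging."""

import numpy as np
import pandas as pd
import pytest

import _oracles as orc
from conftest import rates_and_weights
from bivlogit.simulate import SimulationConfig, make_zone_lattice
from bivlogit.spatial import (VariogramModel, ZoneRates, autocovariate,
                              build_weights, global_morans_i, krige_rates,
                              local_gi_star, local_moran, zone_rates)


def _lattice(nr, nc):
    cfg = SimulationConfig(n_zones=nr * nc, lattice_dims=(nr, nc),
                           clusters_per_zone=1, women_per_cluster=1,
                           beta1=[0.0], beta2=[0.0])
    return make_zone_lattice(cfg)


class TestWeights:
    def test_two_zone_binary_and_row_standardized(self):
        zones = _lattice(1, 2)
        wb = build_weights(zones, "binary")
        assert np.array_equal(wb.w, [[0, 1], [1, 0]])
        wr = build_weights(zones, "row_standardized")
        assert np.array_equal(wr.w, [[0, 1], [1, 0]])

    def test_path_row_standardized_middle(self):
        zones = _lattice(1, 3)
        wr = build_weights(zones, "row_standardized")
        assert np.allclose(wr.w[1], [0.5, 0, 0.5])

    def test_zero_diagonal_and_styles(self):
        zones = _lattice(3, 3)
        for style in ("binary", "row_standardized"):
            w = build_weights(zones, style).w
            assert np.all(np.diag(w) == 0)
        rs = build_weights(zones, "row_standardized").w
        assert np.allclose(rs.sum(axis=1), 1.0)


class TestZoneRatesAndAutocovariate:
    def test_unweighted_and_weighted_rates(self):
        df = pd.DataFrame({"zone_id": [0, 0, 0, 0, 1, 1],
                           "y1": [1, 1, 0, 0, 1, 0],
                           "weight": [1, 1, 1, 1, 3, 1]})
        r_unw = zone_rates(df, "y1", weighted=False)
        assert r_unw.rates[0] == 0.5
        r_w = zone_rates(df, "y1", weighted=True)
        assert r_w.rates[1] == 0.75

    def test_all_ones_zone(self):
        df = pd.DataFrame({"zone_id": [0, 0], "y1": [1, 1], "weight": [1, 1]})
        assert zone_rates(df, "y1").rates[0] == 1.0

    def test_neighbor_average(self):
        zones = _lattice(1, 3)
        w = build_weights(zones, "binary")
        zr = ZoneRates(rates={0: 0.2, 1: 0.4, 2: 0.9},
                       denominators={0: 1, 1: 1, 2: 1})
        si = autocovariate(zr, w)
        assert si[1] == pytest.approx((0.2 + 0.9) / 2)
        assert si[0] == pytest.approx(0.4)

    def test_constant_neighbors(self):
        zones = _lattice(2, 2)
        w = build_weights(zones, "binary")
        zr = ZoneRates(rates={i: 0.37 for i in range(4)},
                       denominators={i: 1 for i in range(4)})
        assert all(v == pytest.approx(0.37) for v in autocovariate(zr, w).values())

    def test_island_falls_back_to_global_mean(self):
        from bivlogit.spatial import SpatialWeights
        w = SpatialWeights(zone_order=[0, 1, 2],
                           w=np.array([[0, 1, 0], [1, 0, 0], [0, 0, 0.0]]),
                           style="binary")
        zr = ZoneRates(rates={0: 0.2, 1: 0.4, 2: 0.69},
                       denominators={0: 1, 1: 1, 2: 1})
        si = autocovariate(zr, w)
        assert si[2] == pytest.approx(np.mean([0.2, 0.4, 0.69]))

    def test_bounded_by_neighbor_rates(self):
        rng = np.random.default_rng(0)
        y, a = orc.random_spatial_instance(rng)
        zr, wb, _ = rates_and_weights(y, a)
        si = autocovariate(zr, wb)
        for i in range(len(y)):
            nb = [y[j] for j in range(len(y)) if a[i][j]]
            assert min(nb) - 1e-12 <= si[i] <= max(nb) + 1e-12


class TestGlobalMoran:
    def test_checkerboard_is_minus_one(self):
        zones = _lattice(4, 4)
        wr = build_weights(zones, "row_standardized")
        y = np.array([(z.zone_id // 4 + z.zone_id % 4) % 2 for z in zones], float)
        zr = ZoneRates(rates={z.zone_id: y[i] for i, z in enumerate(zones)},
                       denominators={z.zone_id: 1 for z in zones})
        res = global_morans_i(zr, wr, n_perm=99, seed=0)
        assert res.i == pytest.approx(-1.0, abs=1e-12)
        assert res.expected_i == pytest.approx(-1 / 15)

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            y, a = orc.random_spatial_instance(rng)
            zr, _, wr = rates_and_weights(y, a)
            res = global_morans_i(zr, wr, n_perm=9, seed=0)
            assert res.i == pytest.approx(
                orc.naive_morans_i(list(y), wr.w.tolist()), abs=1e-12)

    def test_permutation_p_calibrated_under_null(self):
        zones = _lattice(4, 4)
        wr = build_weights(zones, "row_standardized")
        rng = np.random.default_rng(23)
        rejections = 0
        n_rep = 200
        for _ in range(n_rep):
            y = rng.random(16)
            zr = ZoneRates(rates={i: y[i] for i in range(16)},
                           denominators={i: 1 for i in range(16)})
            res = global_morans_i(zr, wr, n_perm=199,
                                  seed=int(rng.integers(2 ** 31)))
            if res.p_perm <= 0.05:
                rejections += 1
        assert 0.02 <= rejections / n_rep <= 0.09

    def test_reproducible_and_bounded_p(self):
        rng = np.random.default_rng(3)
        y, a = orc.random_spatial_instance(rng)
        zr, _, wr = rates_and_weights(y, a)
        r1 = global_morans_i(zr, wr, n_perm=99, seed=42)
        r2 = global_morans_i(zr, wr, n_perm=99, seed=42)
        assert r1.p_perm == r2.p_perm
        assert 1 / 100 <= r1.p_perm <= 1.0

    def test_constant_rates_rejected(self):
        zones = _lattice(2, 2)
        wr = build_weights(zones, "row_standardized")
        zr = ZoneRates(rates={i: 0.5 for i in range(4)},
                       denominators={i: 1 for i in range(4)})
        with pytest.raises(ValueError, match="variance"):
            global_morans_i(zr, wr, n_perm=9, seed=0)


class TestGiStar:
    def test_single_hot_zone_on_lattice(self):
        zones = _lattice(5, 5)
        wb = build_weights(zones, "binary")
        y = np.zeros(25)
        y[12] = 1.0  # center
        zr = ZoneRates(rates={i: y[i] for i in range(25)},
                       denominators={i: 1 for i in range(25)})
        res = local_gi_star(zr, wb)
        z = dict(zip(res.zone_order, res.z))
        hot = {12, 7, 11, 13, 17}  # center and its rook neighbors
        assert z[12] == max(z.values())
        threshold = max(z[i] for i in range(25) if i not in hot)
        assert all(z[i] > threshold for i in hot)

    def test_matches_textbook_oracle(self):
        rng = np.random.default_rng(13)
        for _ in range(50):
            y, a = orc.random_spatial_instance(rng)
            zr, wb, _ = rates_and_weights(y, a)
            res = local_gi_star(zr, wb)
            ref = np.array(orc.naive_gi_star(list(y), a.tolist()))
            assert np.allclose(res.z, ref, atol=1e-12, equal_nan=True)

    def test_constant_rates_rejected(self):
        zones = _lattice(2, 2)
        wb = build_weights(zones, "binary")
        zr = ZoneRates(rates={i: 0.3 for i in range(4)},
                       denominators={i: 1 for i in range(4)})
        with pytest.raises(ValueError, match="variance"):
            local_gi_star(zr, wb)

    def test_category_consistency(self):
        rng = np.random.default_rng(17)
        y, a = orc.random_spatial_instance(rng)
        zr, wb, _ = rates_and_weights(y, a)
        res = local_gi_star(zr, wb)
        for zi, cat in zip(res.z, res.category):
            if cat.startswith("hotspot"):
                assert zi >= 1.645
            elif cat.startswith("coldspot"):
                assert zi <= -1.645
            else:
                assert abs(zi) < 1.645


class TestLocalMoran:
    def test_checkerboard_outliers(self):
        zones = _lattice(4, 4)
        wr = build_weights(zones, "row_standardized")
        y = np.array([(z.zone_id // 4 + z.zone_id % 4) % 2 for z in zones], float)
        zr = ZoneRates(rates={i: y[i] for i in range(16)},
                       denominators={i: 1 for i in range(16)})
        res = local_moran(zr, wr, n_perm=199, seed=0)
        sig = [c for c in res.category if c != "NS"]
        assert sig and all(c in ("HL", "LH") for c in sig)

    def test_high_block_typed_hh(self):
        zones = _lattice(6, 6)
        wr = build_weights(zones, "row_standardized")
        block = {0, 1, 6, 7}  # uniform 2x2 high corner
        y = np.array([0.9 if z.zone_id in block else 0.1 for z in zones])
        zr = ZoneRates(rates={i: y[i] for i in range(36)},
                       denominators={i: 1 for i in range(36)})
        res = local_moran(zr, wr, n_perm=499, seed=1)
        cat = dict(zip(res.zone_order, res.category))
        assert cat[0] == "HH"

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(19)
        for _ in range(50):
            y, a = orc.random_spatial_instance(rng)
            zr, _, wr = rates_and_weights(y, a)
            res = local_moran(zr, wr, n_perm=9, seed=0)
            assert np.allclose(res.statistic,
                               orc.naive_local_moran(list(y), wr.w.tolist()),
                               atol=1e-12)

    def test_mean_local_equals_global(self):
        rng = np.random.default_rng(29)
        y, a = orc.random_spatial_instance(rng)
        zr, _, wr = rates_and_weights(y, a)
        res = local_moran(zr, wr, n_perm=9, seed=0)
        glob = global_morans_i(zr, wr, n_perm=9, seed=0).i
        n = len(y)
        assert np.mean(res.statistic) * n / (n - 1) == pytest.approx(glob, abs=1e-10)

    def test_p_bounds_and_reproducibility(self):
        rng = np.random.default_rng(31)
        y, a = orc.random_spatial_instance(rng)
        zr, _, wr = rates_and_weights(y, a)
        r1 = local_moran(zr, wr, n_perm=99, seed=5)
        r2 = local_moran(zr, wr, n_perm=99, seed=5)
        assert np.array_equal(r1.p, r2.p)
        assert np.all(r1.p >= 1 / 100) and np.all(r1.p <= 1.0)


class TestKriging:
    def _zr(self, vals):
        return ZoneRates(rates={i: v for i, v in enumerate(vals)},
                         denominators={i: 1 for i in range(len(vals))})

    def test_constant_field_predicts_constant(self):
        zones = _lattice(3, 3)
        res = krige_rates(self._zr([0.42] * 9), zones, n_grid=5)
        assert np.allclose(res.prediction, 0.42, atol=1e-10)

    def test_exact_interpolation_with_zero_nugget(self):
        zones = _lattice(3, 3)
        vals = [0.1, 0.3, 0.5, 0.2, 0.8, 0.4, 0.6, 0.9, 0.05]
        coords = np.array([z.centroid for z in zones])
        res = krige_rates(self._zr(vals), zones,
                          grid=(coords[:, 0], coords[:, 1]),
                          variogram=VariogramModel(0.0, 0.2, 1.5))
        assert np.allclose(res.prediction, vals, atol=1e-8)

    def test_midpoint_weights_half_half(self):
        from bivlogit.simulate import ZoneGeometry
        zones = [ZoneGeometry(0, (0.0, 0.0), (1,)), ZoneGeometry(1, (2.0, 0.0), (0,))]
        res = krige_rates(self._zr([0.2, 0.6]), zones,
                          grid=(np.array([1.0]), np.array([0.0])),
                          variogram=VariogramModel(0.0, 0.3, 1.0))
        assert np.allclose(res.weights[0], [0.5, 0.5], atol=1e-10)
        assert res.prediction[0] == pytest.approx(0.4)

    def test_weights_sum_to_one(self):
        zones = _lattice(4, 4)
        rng = np.random.default_rng(2)
        res = krige_rates(self._zr(rng.random(16)), zones, n_grid=7)
        assert np.allclose(res.weights.sum(axis=1), 1.0, atol=1e-10)

    def test_duplicate_centroids_rejected(self):
        from bivlogit.simulate import ZoneGeometry
        zones = [ZoneGeometry(i, (0.0, 0.0), ()) for i in range(5)]
        with pytest.raises(ValueError, match="duplicate|singular"):
            krige_rates(self._zr([0.1, 0.2, 0.3, 0.4, 0.5]), zones,
                        variogram=VariogramModel(0.0, 0.2, 1.0))

    def test_variogram_fit_is_nonnegative(self):
        zones = _lattice(4, 4)
        rng = np.random.default_rng(8)
        res = krige_rates(self._zr(rng.random(16)), zones, n_grid=3)
        vg = res.variogram
        assert vg.nugget >= 0 and vg.sill >= 0 and vg.range_ > 0
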