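import numpy as np
import pytest
from scipy.stats import chisquare

from areakrig.aggregate import assign_cells
from areakrig.autocorr import idw_weights_matrix, morans_i
from areakrig.core_geo import jitter_duplicates
from areakrig.synthetic_data import (
    AreaPolygons,
    binarize_latent,
    make_region,
    sample_survey_locations,
    simulate_births,
    simulate_grf,
)
from areakrig.variogram import VariogramModel, empirical_variogram, model_gamma
from scipy.special import expit
from tests.conftest import make_pts


class TestMakeRegion:
    def test_counts_and_total_area(self):
        region = make_region(2, 2, 1000.0)
        assert len(region) == 4
        assert sum(g.area for g in region.geometries) == pytest.approx(4e6)
        single = make_region(1, 1, 500.0)
        assert single.geometries[0].bounds == (0.0, 0.0, 500.0, 500.0)

    def test_tiles_are_disjoint_and_cover(self):
        region = make_region(3, 2, 100.0)
        total = sum(g.area for g in region.geometries)
        assert total == pytest.approx(3 * 2 * 100.0**2)
        for i in range(len(region)):
            for j in range(i + 1, len(region)):
                inter = region.geometries[i].intersection(region.geometries[j])
                assert inter.area == 0.0

    def test_geojson_roundtrip(self, tmp_path):
        region = make_region(2, 3, 250.0)
        path = tmp_path / "areas.geojson"
        region.to_geojson(path)
        back = AreaPolygons.from_geojson(path)
        assert list(back.area_ids) == list(region.area_ids)
        assert back.geometries[4].equals(region.geometries[4])


class TestSampleSurveyLocations:
    def test_no_duplicates_when_rate_zero(self):
        region = make_region(5, 5, 1000.0)
        pts = sample_survey_locations(region, n=500, duplicate_rate=0.0, seed=1)
        assert len({(x, y) for x, y in zip(pts.x, pts.y)}) == 500

    def test_uniform_when_urban_share_zero(self):
        region = make_region(5, 5, 1000.0)
        pts = sample_survey_locations(region, n=5000, urban_share=0.0,
                                      duplicate_rate=0.0, seed=2)
        counts = np.bincount(assign_cells(pts.coords, region), minlength=25)
        _, p = chisquare(counts)
        assert p > 0.01

    def test_clustered_sampling_leaves_empty_areas(self):
        region = make_region()  # 648 areas
        for seed in range(10):
            pts = sample_survey_locations(region, n=4086, urban_share=0.8,
                                          seed=seed)
            counts = np.bincount(assign_cells(pts.coords, region),
                                 minlength=len(region))
            assert (counts == 0).any()

    def test_duplicates_share_group_label(self):
        region = make_region(4, 4, 1000.0)
        pts = sample_survey_locations(region, n=300, duplicate_rate=0.3, seed=3)
        coords = list(zip(pts.x, pts.y))
        assert len(set(coords)) < 300
        # co-located points carry the same group label
        seen = {}
        for (xy, g) in zip(coords, pts.group):
            if xy in seen:
                assert seen[xy] == g
            seen[xy] = g

    def test_zero_points_error(self):
        with pytest.raises(ValueError):
            sample_survey_locations(make_region(2, 2, 100.0), n=0)


class TestSimulateGrf:
    def test_bit_identical_given_seed(self, exp_model, random_pts):
        a = simulate_grf(random_pts, exp_model, seed=5)
        b = simulate_grf(random_pts, exp_model, seed=5)
        np.testing.assert_array_equal(a, b)

    def test_pure_nugget_limit_independent(self):
        # near-zero structure: two far-apart points behave independently
        m = VariogramModel("exponential", nugget=4.0, partial_sill=1e-6,
                           range_a=10.0)
        pts = make_pts([0.0, 5000.0], [0.0, 0.0])
        draws = np.array([simulate_grf(pts, m, seed=s) for s in range(5000)])
        var = draws.var(axis=0)
        se = 4.0 * np.sqrt(2.0 / 5000)  # MC SE of a variance estimate
        assert np.all(np.abs(var - 4.0) < 3 * se)
        r = np.corrcoef(draws[:, 0], draws[:, 1])[0, 1]
        assert abs(r) < 3.0 / np.sqrt(5000)

    def test_pair_covariance_matches_model(self, exp_model):
        h = 8000.0
        pts = make_pts([0.0, h], [0.0, 0.0])
        draws = np.array([simulate_grf(pts, exp_model, seed=s)
                          for s in range(10000)])
        expect = exp_model.sill - model_gamma(exp_model, h)
        cov = np.cov(draws[:, 0], draws[:, 1])[0, 1]
        # MC SE of a covariance of bivariate normals
        se = np.sqrt((exp_model.sill**2 + expect**2) / 10000)
        assert abs(cov - expect) < 3 * se

    def test_mean_parameter(self, exp_model):
        rng = np.random.default_rng(0)
        pts = make_pts(rng.uniform(0, 100000, 1000), rng.uniform(0, 100000, 1000))
        z = simulate_grf(pts, exp_model, mean=50.0, seed=1)
        # crude effective sample size: domain is ~5x5 correlation ranges
        n_eff = 25
        assert abs(z.mean() - 50.0) < 3 * np.sqrt(exp_model.sill / n_eff)

    def test_empirical_variogram_matches_model(self, exp_model):
        rng = np.random.default_rng(10)
        n = 2000
        pts = make_pts(rng.uniform(0, 100000, n), rng.uniform(0, 100000, n))
        lag, nl = 2000.0, 10  # lags up to the range
        acc = np.zeros(nl)
        for seed in range(20):
            z = simulate_grf(pts, exp_model, seed=seed)
            acc += empirical_variogram(pts, z, lag, nl).gamma
        mean_gamma = acc / 20
        expect = model_gamma(exp_model, (np.arange(nl) + 0.5) * lag)
        np.testing.assert_allclose(mean_gamma, expect, rtol=0.15)

    def test_coincident_points_rejected(self, exp_model):
        pts = make_pts([0.0, 0.0, 10.0], [0.0, 0.0, 0.0])
        with pytest.raises(ValueError, match="positive semi-definite"):
            simulate_grf(pts, exp_model, seed=0)


class TestBinarizeLatent:
    def test_exact_count_at_half(self):
        rng = np.random.default_rng(3)
        out = binarize_latent(rng.normal(size=100), 0.5)
        assert out.sum() == 50

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(4)
        z = rng.normal(size=200)
        np.testing.assert_array_equal(binarize_latent(z, 0.3),
                                      binarize_latent(np.exp(z), 0.3))

    def test_spatial_binary_keeps_positive_morans_i(self, exp_model):
        rng = np.random.default_rng(7)
        n = 2000
        pts = make_pts(rng.uniform(0, 60000, n), rng.uniform(0, 60000, n))
        pts = jitter_duplicates(pts, seed=0)
        z = simulate_grf(pts, exp_model, seed=11)
        b = binarize_latent(z, 0.3).astype(float)
        W = idw_weights_matrix(pts, power=2, threshold=6000.0)
        res = morans_i(b, W)
        assert res.z > 1.96

    def test_constant_latent_errors(self):
        with pytest.raises(ValueError):
            binarize_latent(np.ones(10), 0.5)


class TestSimulateBirths:
    def test_null_model_rate_half(self, small_region):
        births = simulate_births(small_region, np.zeros(len(small_region)),
                                 gamma00=0.0, gamma01=0.0, sigma_u=0.0,
                                 betas=np.zeros(5),
                                 covariate_prevalences=(0.5,) * 5,
                                 n_per_area=2000, seed=0)
        n = len(births)
        assert abs(births.LBW.mean() - 0.5) < 3 * np.sqrt(0.25 / n)

    def test_intercept_only_rate(self, small_region):
        births = simulate_births(small_region, np.zeros(len(small_region)),
                                 gamma00=-3.0, gamma01=0.0, sigma_u=0.0,
                                 betas=np.zeros(5),
                                 covariate_prevalences=(0.5,) * 5,
                                 n_per_area=3000, seed=1)
        p = expit(-3.0)
        n = len(births)
        assert abs(births.LBW.mean() - p) < 3 * np.sqrt(p * (1 - p) / n)

    def test_area_log_odds_slope_recovers_gamma01(self):
        region = make_region(6, 5, 1000.0)
        rng = np.random.default_rng(9)
        risk = rng.normal(0.0, 1.0, len(region))
        g01 = 0.7
        births = simulate_births(region, risk, gamma00=-1.0, gamma01=g01,
                                 sigma_u=0.0, betas=np.zeros(5),
                                 covariate_prevalences=(0.5,) * 5,
                                 n_per_area=4000, seed=2)
        rates = births.groupby("area_id")["LBW"].mean()
        risk_by_area = dict(zip(region.area_ids, risk))
        x = np.array([risk_by_area[a] for a in rates.index])
        logodds = np.log(rates / (1 - rates))
        slope = np.polyfit(x, logodds, 1)[0]
        assert slope == pytest.approx(g01, rel=0.1)

    def test_no_overdispersion_without_random_effect(self, small_region):
        births = simulate_births(small_region, np.zeros(len(small_region)),
                                 gamma00=-1.0, gamma01=0.0, sigma_u=0.0,
                                 betas=np.zeros(5),
                                 covariate_prevalences=(0.5,) * 5,
                                 n_per_area=500, seed=3)
        counts = births.groupby("area_id")["LBW"].sum()
        p = births.LBW.mean()
        n = 500
        # Pearson dispersion statistic ~ chi2(J-1) under pure binomial sampling
        stat = float(((counts - n * p) ** 2 / (n * p * (1 - p))).sum())
        from scipy.stats import chi2

        J = len(small_region)
        assert chi2.sf(stat, J - 1) > 0.01

    def test_deterministic(self, small_region):
        kw = dict(nb_risk=np.zeros(len(small_region)), n_per_area=10, seed=12)
        a = simulate_births(small_region, **kw)
        b = simulate_births(small_region, **kw)
        assert a.equals(b)
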