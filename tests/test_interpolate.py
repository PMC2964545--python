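import numpy as np
import pytest

from areakrig.core_geo import knn
from areakrig.interpolate import (
    NeighborhoodSpec,
    fit_trend,
    idw_predict,
    ok_predict,
    ok_system,
    select_neighbors,
    uk_predict,
)
from areakrig.synthetic_data import simulate_grf
from areakrig.variogram import VariogramModel, model_gamma
from tests.conftest import make_pts


def full_ok_solve(coords, values, query, model):
    """Independent dense ordinary-kriging solve (reference implementation)."""
    m = len(coords)
    A = np.ones((m + 1, m + 1))
    A[m, m] = 0.0
    for i in range(m):
        for j in range(m):
            h = np.hypot(*(coords[i] - coords[j]))
            A[i, j] = model_gamma(model, h)
    g0 = np.array([model_gamma(model, np.hypot(*(coords[i] - np.asarray(query))))
                   for i in range(m)])
    sol = np.linalg.solve(A, np.append(g0, 1.0))
    w, lam = sol[:m], sol[m]
    return float(w @ values), float(w @ g0 + lam), w


class TestSelectNeighbors:
    def test_knn_delegates_to_core(self, random_pts):
        q = (320.0, 110.0)
        spec = NeighborhoodSpec(strategy="knn", k=7)
        idx, d = select_neighbors(random_pts, q, spec)
        idx2, d2 = knn(random_pts, q, 7)
        np.testing.assert_array_equal(idx, idx2)
        np.testing.assert_allclose(d, d2)

    def test_circle_invariant_to_azimuth(self, random_pts):
        q = (500.0, 500.0)
        a = select_neighbors(random_pts, q, NeighborhoodSpec(
            strategy="ellipse", semi_major=400.0, semi_minor=400.0,
            azimuth_deg=0.0, k=50))[0]
        b = select_neighbors(random_pts, q, NeighborhoodSpec(
            strategy="ellipse", semi_major=400.0, semi_minor=400.0,
            azimuth_deg=63.0, k=50))[0]
        np.testing.assert_array_equal(sorted(a), sorted(b))

    def test_sector_quota_one_per_axis(self):
        # one point on each half-axis; 4 sectors, quota 1 -> all four chosen
        pts = make_pts([10.0, -20.0, 0.0, 0.0, 30.0],
                       [0.0, 0.0, 15.0, -25.0, 40.0])
        spec = NeighborhoodSpec(strategy="sector", n_sectors=4, quota=1, k=4)
        idx, _ = select_neighbors(pts, (0.0, 0.0), spec)
        assert len(idx) == 4
        assert set(idx) <= {0, 1, 2, 3, 4}
        # the nearest point in each quadrant is selected
        assert {0, 1} <= set(idx)

    def test_exclude_drops_target(self, random_pts):
        q = (random_pts.x[3], random_pts.y[3])
        idx, _ = select_neighbors(random_pts, q,
                                  NeighborhoodSpec(k=len(random_pts) - 1),
                                  exclude=3)
        assert 3 not in idx


class TestIdwPredict:
    def test_direct_formula(self):
        pred = idw_predict((0.0, 0.0), np.array([[1.0, 0.0], [2.0, 0.0]]),
                           np.array([0.0, 10.0]), power=1.0)
        assert pred.value == pytest.approx(10.0 / 3.0)
        assert pred.se is None

    def test_exact_at_sample(self):
        coords = np.array([[1.0, 1.0], [5.0, 5.0]])
        pred = idw_predict((1.0, 1.0), coords, np.array([3.0, 9.0]))
        assert pred.value == 3.0

    def test_liszka_large_delta2_tends_to_mean(self):
        coords = np.array([[1.0, 0.0], [2.0, 0.0], [7.0, 0.0]])
        vals = np.array([1.0, 5.0, 9.0])
        pred = idw_predict((0.0, 0.0), coords, vals, power=2.0,
                           variant="liszka", delta2=1e9 * 7.0)
        assert pred.value == pytest.approx(vals.mean(), rel=1e-6)

    def test_within_neighbor_range(self, random_pts):
        vals = random_pts.variable("v")
        pred = idw_predict((432.0, 510.0), random_pts.coords, vals, power=2.0)
        assert vals.min() <= pred.value <= vals.max()

    def test_conflicting_colocated_values_error(self):
        coords = np.array([[0.0, 0.0], [0.0, 0.0]])
        with pytest.raises(ValueError, match="jitter"):
            idw_predict((0.0, 0.0), coords, np.array([1.0, 2.0]))


class TestOkSystem:
    def test_single_neighbor_weight_one(self, exp_model):
        w, lam, _ = ok_system(np.array([[100.0, 100.0]]), (0.0, 0.0), exp_model)
        assert w[0] == pytest.approx(1.0)

    def test_symmetric_pair_equal_weights(self, exp_model):
        coords = np.array([[-50.0, 0.0], [50.0, 0.0]])
        w, _, _ = ok_system(coords, (0.0, 10.0), exp_model)
        np.testing.assert_allclose(w, [0.5, 0.5], atol=1e-12)

    def test_matches_independent_dense_solve(self, exp_model):
        rng = np.random.default_rng(21)
        coords = rng.uniform(0, 5000, (5, 2))
        vals = rng.normal(50, 5, 5)
        q = (2500.0, 2500.0)
        w, lam, g0 = ok_system(coords, q, exp_model)
        ref_val, ref_var, ref_w = full_ok_solve(coords, vals, q, exp_model)
        np.testing.assert_allclose(w, ref_w, atol=1e-8)
        assert float(w @ vals) == pytest.approx(ref_val, abs=1e-8)

    def test_weights_sum_to_one(self, exp_model):
        rng = np.random.default_rng(22)
        for _ in range(10):
            coords = rng.uniform(0, 30000, (12, 2))
            w, _, _ = ok_system(coords, tuple(rng.uniform(0, 30000, 2)), exp_model)
            assert abs(w.sum() - 1.0) < 1e-8


class TestOkPredict:
    def test_exact_at_datum_with_zero_se(self, random_pts, exp_model):
        i = 7
        pred = ok_predict((random_pts.x[i], random_pts.y[i]), random_pts, "v",
                          exp_model, spec=NeighborhoodSpec(k=10))
        assert pred.value == random_pts.variable("v")[i]
        assert pred.se == 0.0

    def test_far_query_variance_exceeds_sill(self, exp_model):
        rng = np.random.default_rng(23)
        pts = make_pts(rng.uniform(0, 1000, 30), rng.uniform(0, 1000, 30),
                       values={"v": rng.normal(10, 2, 30)})
        pred = ok_predict((500.0 + 2e6, 500.0), pts, "v", exp_model,
                          spec=NeighborhoodSpec(k=30))
        assert pred.se**2 >= exp_model.sill

    def test_pure_nugget_gives_neighbor_mean(self):
        m = VariogramModel("exponential", nugget=5.0, partial_sill=1e-9,
                           range_a=10.0)
        rng = np.random.default_rng(24)
        pts = make_pts(rng.uniform(0, 1000, 15), rng.uniform(0, 1000, 15),
                       values={"v": rng.normal(0, 1, 15)})
        pred = ok_predict((480.0, 520.0), pts, "v", m,
                          spec=NeighborhoodSpec(k=15))
        assert pred.value == pytest.approx(pts.variable("v").mean(), abs=1e-5)

    def test_neighborhood_k_equals_n_matches_full_solve(self, exp_model):
        rng = np.random.default_rng(25)
        n = 40
        pts = make_pts(rng.uniform(0, 20000, n), rng.uniform(0, 20000, n),
                       values={"v": rng.normal(50, 5, n)})
        q = (9000.0, 11000.0)
        pred = ok_predict(q, pts, "v", exp_model, spec=NeighborhoodSpec(k=n))
        ref_val, ref_var, _ = full_ok_solve(pts.coords, pts.variable("v"), q,
                                            exp_model)
        assert pred.value == pytest.approx(ref_val, abs=1e-8)
        assert pred.se**2 == pytest.approx(ref_var, abs=1e-8)

    def test_duplicate_neighbors_error(self, exp_model):
        pts = make_pts([0.0, 0.0, 10.0], [0.0, 0.0, 0.0],
                       values={"v": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="jitter"):
            ok_predict((5.0, 5.0), pts, "v", exp_model,
                       spec=NeighborhoodSpec(k=3))


class TestUkPredict:
    def test_planar_data_reproduced(self, exp_model):
        rng = np.random.default_rng(26)
        n = 50
        pts = make_pts(rng.uniform(0, 1000, n), rng.uniform(0, 1000, n))
        vals = 2.0 + 0.01 * pts.x - 0.005 * pts.y
        q = (321.0, 654.0)
        pred = uk_predict(q, pts, vals, exp_model, trend_order=1,
                          spec=NeighborhoodSpec(k=n))
        assert pred.value == pytest.approx(2.0 + 0.01 * q[0] - 0.005 * q[1],
                                           abs=1e-6)

    def test_zero_trend_equals_ok(self, exp_model):
        rng = np.random.default_rng(27)
        n = 200
        pts = make_pts(rng.uniform(0, 60000, n), rng.uniform(0, 60000, n))
        z = simulate_grf(pts, exp_model, mean=50.0, seed=4)
        q = (30000.0, 30000.0)
        ok = ok_predict(q, pts, z, exp_model, spec=NeighborhoodSpec(k=50))
        uk = uk_predict(q, pts, z, exp_model, trend_order=1,
                        spec=NeighborhoodSpec(k=50))
        # flat generating surface: trend coefficients ~ 0, predictions agree
        assert uk.value == pytest.approx(ok.value, abs=0.35)

    def test_order2_needs_six_points(self, exp_model):
        pts = make_pts([0, 1, 2, 3, 4.0], [0, 1, 0, 1, 0.0])
        with pytest.raises(ValueError, match="6 points"):
            uk_predict((1.0, 1.0), pts, np.zeros(5), exp_model, trend_order=2,
                       spec=NeighborhoodSpec(k=5))

    def test_rank_deficient_trend_errors(self):
        # collinear geometry cannot identify a planar trend in y
        pts = make_pts(np.arange(10.0), np.zeros(10))
        with pytest.raises(ValueError, match="rank-deficient"):
            fit_trend(pts, np.arange(10.0), order=1)


def test_kriging_variance_nonnegative_everywhere(exp_model):
    rng = np.random.default_rng(30)
    n = 60
    pts = make_pts(rng.uniform(0, 10000, n), rng.uniform(0, 10000, n),
                   values={"v": rng.normal(0, 3, n)})
    for _ in range(20):
        q = tuple(rng.uniform(-2000, 12000, 2))
        pred = ok_predict(q, pts, "v", exp_model, spec=NeighborhoodSpec(k=20))
        assert pred.se >= 0.0
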