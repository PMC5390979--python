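import itertools
import math

import numpy as np
import pytest

from pfe.catch_model import (
    capacity_report,
    fit_catch_model,
    inflection_point,
    mantel_test,
    predict_catch,
)

from .conftest import make_cells


def catch_cells(rng, n, K, b, sigma, pfe_range=(2.0, 120.0)):
    pfe = rng.uniform(*pfe_range, n)
    catch = K * np.exp(-b / pfe) * np.exp(rng.normal(0.0, sigma, n))
    ids = range(n)
    return make_cells(dict(zip(ids, pfe))), make_cells(dict(zip(ids, catch)))


class TestPredictCatch:
    def test_printed_parameters_at_inflection(self):
        # K = 2204, b = 47: catch at the plateau onset is 2204 e^-2
        assert predict_catch(23.5, 2204.0, 47.0) == pytest.approx(
            2204.0 * math.exp(-2.0)
        )
        assert round(predict_catch(23.5, 2204.0, 47.0)) == 298

    def test_limits(self):
        assert predict_catch(0.0, 2204.0, 47.0) == 0.0
        assert predict_catch(1e12, 2204.0, 47.0) == pytest.approx(2204.0, rel=1e-9)

    def test_direct_evaluation(self):
        assert predict_catch(47.0, 2204.0, 47.0) == pytest.approx(
            2204.0 * math.exp(-1.0)
        )

    def test_monotone_and_bounded(self):
        x = np.linspace(0.1, 500, 1000)
        y = predict_catch(x, 2204.0, 47.0)
        assert (np.diff(y) > 0).all()
        assert (y < 2204.0).all() and (y > 0).all()

    def test_curvature_switches_at_b_over_2(self):
        # convex below b/2, concave above (numeric second difference)
        b = 47.0
        x = np.linspace(1.0, 120.0, 4000)
        y = predict_catch(x, 2204.0, b)
        d2 = np.diff(y, 2)
        mid = x[1:-1]
        assert (d2[mid < b / 2 - 0.5] > 0).all()
        assert (d2[mid > b / 2 + 0.5] < 0).all()

    def test_bad_parameters_rejected(self):
        with pytest.raises(ValueError):
            predict_catch(10.0, -1.0, 47.0)


class TestFitCatchModel:
    def test_noiseless_exact_recovery(self, rng):
        pfe, catch = catch_cells(rng, 300, K=1000.0, b=20.0, sigma=0.0)
        fit = fit_catch_model(pfe, catch, n_draws=20, draw_size=250, seed=1)
        assert fit.K == pytest.approx(1000.0, abs=1e-6)
        assert fit.b == pytest.approx(20.0, abs=1e-6)
        # all draws identical on noiseless data
        Ks = [d["K"] for d in fit.per_draw]
        assert max(Ks) - min(Ks) < 1e-6
        assert fit.r2 == pytest.approx(1.0, abs=1e-9)

    def test_log_and_arithmetic_forms_agree(self, rng):
        # exponentiating the log-scale fit reproduces the arithmetic curve
        pfe, catch = catch_cells(rng, 300, K=2204.0, b=47.0, sigma=0.0)
        fit = fit_catch_model(pfe, catch, n_draws=5, draw_size=250, seed=2)
        p = pfe.values.to_numpy()
        np.testing.assert_allclose(
            predict_catch(p, fit.K, fit.b), catch.values.to_numpy(), rtol=1e-6
        )

    def test_zero_pfe_cells_excluded(self, rng):
        pfe, catch = catch_cells(rng, 260, K=1000.0, b=20.0, sigma=0.0)
        pfe.values.iloc[0] = 0.0
        catch.values.iloc[0] = 0.0
        with pytest.warns(UserWarning, match="excluded"):
            fit = fit_catch_model(pfe, catch, n_draws=5, draw_size=250, seed=3)
        assert fit.n_zero_pfe_excluded == 1
        assert fit.n_cells_used == 259

    def test_draw_size_exceeding_cells_rejected(self, rng):
        pfe, catch = catch_cells(rng, 100, K=1000.0, b=20.0, sigma=0.0)
        with pytest.raises(ValueError, match="draw_size"):
            fit_catch_model(pfe, catch, n_draws=5, draw_size=250, seed=4)

    def test_seed_required_and_reproducible(self, rng):
        pfe, catch = catch_cells(rng, 300, K=1000.0, b=20.0, sigma=0.3)
        with pytest.raises(ValueError, match="seed"):
            fit_catch_model(pfe, catch, n_draws=5, draw_size=250)
        f1 = fit_catch_model(pfe, catch, n_draws=10, draw_size=250, seed=5)
        f2 = fit_catch_model(pfe, catch, n_draws=10, draw_size=250, seed=5)
        assert f1.K == f2.K and f1.b == f2.b

    def test_recovery_within_own_ci_under_noise(self):
        # multiplicative lognormal noise sigma = 0.3, n = 565 cells: the
        # reported mean K should fall inside its own mean 95% CI in most
        # seeded replicates
        hits, n_rep = 0, 20
        for rep in range(n_rep):
            rng = np.random.default_rng(300 + rep)
            pfe, catch = catch_cells(rng, 565, K=2204.0, b=47.0, sigma=0.3)
            fit = fit_catch_model(pfe, catch, n_draws=30, draw_size=250, seed=rep)
            if fit.ci_K[0] <= fit.K <= fit.ci_K[1]:
                hits += 1
        assert hits >= 0.9 * n_rep

    def test_per_draw_mantel_attached_when_locations_given(self, rng):
        pfe, catch = catch_cells(rng, 300, K=1000.0, b=20.0, sigma=0.2)
        locs = rng.uniform(0, 1e5, (300, 2))
        fit = fit_catch_model(
            pfe, catch, n_draws=3, draw_size=250, seed=6,
            locations=locs, mantel_n_perm=49,
        )
        for d in fit.per_draw:
            assert "mantel_p" in d and 0 < d["mantel_p"] <= 1


class TestMantel:
    def test_identical_matrices_r_one(self, rng):
        # residuals equal to the x-coordinate of collinear points: the
        # two condensed matrices coincide, so r = 1
        x = rng.uniform(0, 100, 12)
        locs = np.column_stack([x, np.zeros(12)])
        r, p = mantel_test(x, locs, n_perm=99, seed=0)
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_four_point_p_matches_exact_enumeration(self, rng):
        from scipy.spatial.distance import pdist

        resid = np.array([0.3, -1.2, 0.7, 2.0])
        locs = rng.uniform(0, 10, (4, 2))
        d_geo = pdist(locs)

        def corr(v):
            d = pdist(v[:, None], metric="cityblock")
            return np.corrcoef(d, d_geo)[0, 1]

        r_obs = corr(resid)
        # brute-force oracle over all 24 label permutations
        exact = np.mean(
            [corr(resid[list(perm)]) >= r_obs - 1e-12
             for perm in itertools.permutations(range(4))]
        )
        r, p = mantel_test(resid, locs, n_perm=4999, seed=1)
        assert r == pytest.approx(r_obs, abs=1e-12)
        assert p == pytest.approx(exact, abs=0.03)

    def test_statistic_matches_skbio(self, rng):
        from scipy.spatial.distance import pdist, squareform
        from skbio.stats.distance import DistanceMatrix, mantel as skbio_mantel

        resid = rng.normal(0, 1, 15)
        locs = rng.uniform(0, 100, (15, 2))
        r, _ = mantel_test(resid, locs, n_perm=9, seed=0)
        dm_res = DistanceMatrix(squareform(pdist(resid[:, None], metric="cityblock")))
        dm_geo = DistanceMatrix(squareform(pdist(locs)))
        r_ref, _, _ = skbio_mantel(dm_res, dm_geo, method="pearson", permutations=0)
        assert r == pytest.approx(float(r_ref), abs=1e-9)

    def test_type_one_error_near_nominal(self):
        # residuals independent of location: p < 0.05 in ~5% of replicates
        n_rep, rejections = 200, 0
        for rep in range(n_rep):
            rng = np.random.default_rng(5000 + rep)
            resid = rng.normal(0, 1, 50)
            locs = rng.uniform(0, 100, (50, 2))
            _, p = mantel_test(resid, locs, n_perm=99, seed=rep)
            if p < 0.05:
                rejections += 1
        assert 0.01 <= rejections / n_rep <= 0.10

    def test_constant_residuals_rejected(self, rng):
        with pytest.raises(ValueError):
            mantel_test(np.ones(10), rng.uniform(0, 1, (10, 2)), n_perm=9, seed=0)

    def test_too_few_points_rejected(self, rng):
        with pytest.raises(ValueError):
            mantel_test(np.array([1.0, 2.0, 3.0]), rng.uniform(0, 1, (3, 2)))


class TestInflectionAndCapacity:
    @pytest.mark.parametrize("b,expected", [(47.0, 23.5), (2.0, 1.0)])
    def test_inflection_analytic(self, b, expected):
        assert inflection_point(b) == expected

    def test_inflection_matches_numeric_grid(self):
        # dense numeric second derivative of K e^(-b/x) changes sign at b/2
        b, K = 10.0, 500.0
        x = np.linspace(0.5, 30.0, 300_001)
        y = K * np.exp(-b / x)
        d2 = np.diff(y, 2)
        i = np.argmax(d2 < 0)  # first concave point
        assert x[i + 1] == pytest.approx(b / 2.0, abs=1e-3)
        assert inflection_point(b) == pytest.approx(5.0, abs=1e-6)

    def test_bad_b_rejected(self):
        with pytest.raises(ValueError):
            inflection_point(0.0)

    def test_published_capacity_chain(self):
        report = capacity_report(
            (2204.0, 47.0), n_cells=565, cell_area_km2=500.0, observed_fleet=17_839
        )
        assert report.pfe_inflection == 23.5
        assert round(report.catch_at_inflection) == 298
        assert report.area_km2 == 282_500.0
        assert report.fleet_capacity == 13_277  # truncation of 13,277.5
        assert report.excess_boats == 4_562
        assert report.excess_percent == 34

    def test_no_excess_when_fleet_at_capacity(self):
        report = capacity_report((2204.0, 47.0), n_cells=565, observed_fleet=13_277)
        assert report.excess_boats == 0
        assert report.excess_percent == 0

    def test_larger_fleet_estimate(self):
        report = capacity_report((2204.0, 47.0), n_cells=565, observed_fleet=25_000)
        assert report.excess_percent == 88

    def test_zero_capacity_rejected(self):
        with pytest.raises(ValueError):
            capacity_report((100.0, 0.5), n_cells=1, observed_fleet=10)
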