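import math

import numpy as np
import pytest
from scipy import stats

import premirdist as pm
from premirdist.distfit import DistanceDistribution, FAMILIES


class TestNormalFit:
    def test_two_point_closed_form(self):
        fit = pm.fit_normal([0.0, 2.0])
        assert fit.mu == 1.0
        assert fit.sigma == pytest.approx(math.sqrt(2.0), abs=1e-15)

    def test_constant_sample_flagged_degenerate(self):
        fit = pm.fit_normal([3.0, 3.0, 3.0])
        assert fit.sigma == 0.0
        assert fit.degenerate
        assert fit.cdf(3.0) == 1.0 and fit.cdf(2.9) == 0.0

    def test_matches_scipy_mle_location(self):
        rng = np.random.default_rng(1)
        x = rng.normal(2.0, 0.5, size=500)
        fit = pm.fit_normal(x)
        loc, _ = stats.norm.fit(x)
        assert fit.mu == pytest.approx(loc, rel=1e-9)

    def test_nonfinite_values_dropped(self):
        fit = pm.fit_normal([0.0, 2.0, np.inf])
        assert fit.mu == 1.0

    def test_too_few_values(self):
        with pytest.raises(ValueError):
            pm.fit_normal([1.0])


class TestExponentialFit:
    def test_mle_is_sample_mean(self):
        assert pm.fit_exponential([2.0, 4.0]).mean == 3.0
        assert pm.fit_exponential([1.0]).mean == 1.0

    def test_negative_values_rejected(self):
        with pytest.raises(ValueError):
            pm.fit_exponential([-1.0, 2.0])


class TestECDFFit:
    def test_step_cdf_direct_count(self):
        fit = pm.fit_ecdf([1.0, 2.0, 3.0])
        assert fit.step_cdf(2.0) == pytest.approx(2 / 3)

    def test_boundary_conventions(self):
        fit = pm.fit_ecdf([1.0, 2.0, 3.0])
        assert fit.cdf(3.0) == 1.0
        assert fit.cdf(1.0 - 1e-9) == 0.0

    def test_midpoint_node_interpolation(self):
        fit = pm.fit_ecdf([1.0, 2.0])
        assert fit.cdf(1.5) == pytest.approx(0.5)

    def test_ties_share_a_node(self):
        fit = pm.fit_ecdf([1.0, 1.0, 2.0, 2.0])
        # midpoint ordinate of the duplicated value 1.0 is (0 + 1)/4 = 0.25
        assert fit.cdf(1.0) == pytest.approx(0.25)

    def test_degenerate_single_point_sampling(self):
        fit = pm.fit_ecdf([5.0])
        assert fit.sample(3, seed=0).tolist() == [5.0, 5.0, 5.0]

    def test_empty_input(self):
        with pytest.raises(ValueError):
            pm.fit_ecdf([])


class TestKDEFit:
    def test_single_point_is_one_gaussian(self):
        fit = pm.fit_kde([2.0], bandwidth=0.5)
        x = np.array([1.0, 2.0, 3.0])
        np.testing.assert_allclose(
            fit.cdf(x), stats.norm.cdf(x, loc=2.0, scale=0.5), atol=1e-12
        )
        assert fit.cdf(2.0) == pytest.approx(0.5)

    def test_two_kernel_symmetry(self):
        fit = pm.fit_kde([0.0, 1.0], bandwidth=0.5)
        assert fit.cdf(0.5) == pytest.approx(0.5, abs=1e-12)

    def test_matches_independent_scipy_kde(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=60)
        h = 0.3
        fit = pm.fit_kde(x, bandwidth=h)
        ref = stats.gaussian_kde(x, bw_method=h / x.std(ddof=1))
        for q in (-1.0, 0.0, 0.7):
            assert fit.cdf(q) == pytest.approx(
                ref.integrate_box_1d(-np.inf, q), abs=1e-9
            )

    def test_grid_mode_agrees_with_exact(self):
        rng = np.random.default_rng(4)
        x = rng.gamma(4.0, 0.25, size=2000)
        exact = pm.fit_kde(x, bandwidth=0.05, exact=True)
        grid = pm.fit_kde(x, bandwidth=0.05, exact=False)
        probe = np.linspace(x.min(), x.max(), 50)
        np.testing.assert_allclose(grid.cdf(probe), exact.cdf(probe),
                                   atol=5e-5)

    def test_kde_cdf_converges_to_step_ecdf(self):
        x = np.arange(10, dtype=float)
        kde = pm.fit_kde(x, bandwidth=1e-6)
        ecdf = pm.fit_ecdf(x)
        probe = x[:-1] + 0.5  # non-data abscissae
        np.testing.assert_allclose(kde.cdf(probe), ecdf.step_cdf(probe),
                                   atol=1e-6)

    def test_density_integrates_to_one(self):
        fit = pm.fit_kde([0.0, 0.5, 2.0], bandwidth=0.2)
        grid = np.linspace(-2, 4, 4001)
        mass = np.trapezoid(fit.pdf(grid), grid)
        assert mass == pytest.approx(1.0, abs=1e-6)

    def test_nonpositive_bandwidth_rejected(self):
        with pytest.raises(ValueError):
            pm.fit_kde([1.0, 2.0], bandwidth=0.0)

    def test_auto_bandwidth_is_normal_reference(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=300)
        fit = pm.fit_kde(x, bandwidth="auto")
        assert fit.bandwidth == pytest.approx(
            pm.normal_reference_bandwidth(x)
        )


class TestSampling:
    def test_reproducibility_across_families(self, study_distances):
        model = DistanceDistribution(study_distances.values)
        for family in FAMILIES:
            fit = model.fit(family)
            a = fit.sample(100, seed=7)
            b = fit.sample(100, seed=7)
            np.testing.assert_array_equal(a, b)

    def test_normal_sample_mean_clt_bound(self):
        fit = pm.fit_normal(np.array([-1.0, 1.0]) * math.sqrt(0.5))
        # mu=0, sigma=1; n=1e5 => 5-sigma bound ~ 0.016
        draw = fit.sample(100_000, seed=2)
        assert abs(draw.mean()) < 0.02

    def test_sample_from_own_fit_passes_ks(self, study_distances):
        """Samples drawn from each fitted model agree with that model."""
        model = DistanceDistribution(study_distances.values)
        for family in FAMILIES:
            fit = model.fit(family)
            passes = 0
            n_seeds = 20
            for seed in range(n_seeds):
                draw = fit.sample(20_000, seed=seed)
                grid = fit.quantile(np.linspace(0.0005, 0.9995, 20_000))
                ks = pm.ks_two_sample(draw, grid)
                passes += ks.p_value > 0.001
            assert passes >= n_seeds - 1, family


class TestQuantileCdfRoundTrip:
    @pytest.mark.parametrize("family", FAMILIES)
    def test_round_trip(self, family, study_distances):
        model = DistanceDistribution(study_distances.values)
        fit = model.fit(family)
        qs = np.arange(0.01, 1.0, 0.01)
        back = np.asarray(fit.cdf(fit.quantile(qs)))
        tol = 1.0 / fit.data_n if family == "ecdf" else 1e-6
        assert np.max(np.abs(back - qs)) <= tol

    @pytest.mark.parametrize("family", FAMILIES)
    def test_cdf_nondecreasing_on_wide_grid(self, family, study_distances):
        model = DistanceDistribution(study_distances.values)
        fit = model.fit(family)
        lo, hi = fit.data_min, fit.data_max
        pad = 4 * (fit.bandwidth if family == "kde" else
                   np.std(model.values))
        grid = np.linspace(lo - pad, hi + pad, 1000)
        values = np.asarray(fit.cdf(grid))
        assert np.all(np.diff(values) >= -1e-12)
        assert values[0] >= 0.0 and values[-1] <= 1.0


class TestKSTwoSample:
    def test_identical_samples(self):
        result = pm.ks_two_sample([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert result.statistic == 0.0
        assert result.p_value == pytest.approx(1.0)

    def test_disjoint_supports(self):
        result = pm.ks_two_sample([0.1, 0.5, 0.9], [10.2, 10.6, 11.0])
        assert result.statistic == 1.0

    def test_shifted_integer_enumeration(self):
        # step functions of {1,2,3,4} and {2,3,4,5} differ by at most 1/4
        result = pm.ks_two_sample([1, 2, 3, 4], [2, 3, 4, 5])
        assert result.statistic == pytest.approx(0.25)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            pm.ks_two_sample([], [1.0])


class TestModelSelection:
    def test_single_family_ranks_first(self, study_distances):
        sel = pm.select_model(study_distances.values, families=["kde"],
                              n_check=66, seed=0)
        assert sel.best_family == "kde"
        assert len(sel.table) == 1

    def test_normal_data_prefers_normal_over_exponential(self):
        rng = np.random.default_rng(17)
        x = rng.normal(5.0, 1.0, size=10_000)
        votes = 0
        for seed in range(20):
            sel = pm.select_model(x, families=["normal", "exponential"],
                                  n_check=66, seed=seed)
            votes += sel.best_family == "normal"
        assert votes >= 11  # majority over 20 seeds

    def test_selection_table_sorted_by_p_value(self, study_distances):
        sel = pm.select_model(study_distances.values, n_check=66, seed=1)
        p = sel.table["p_value"].to_numpy()
        assert np.all(np.diff(p) <= 0)
        assert set(sel.table["family"]) == set(FAMILIES)

    def test_selection_is_seed_reproducible(self, study_distances):
        a = pm.select_model(study_distances.values, n_check=66, seed=9)
        b = pm.select_model(study_distances.values, n_check=66, seed=9)
        assert a.table.equals(b.table)


class TestModelPersistence:
    @pytest.mark.parametrize("family", FAMILIES)
    def test_roundtrip(self, family, tmp_path, study_distances):
        values = study_distances.finite_values()[:500]
        fit = DistanceDistribution(values).fit(family)
        path = tmp_path / f"{family}.json"
        pm.save_model(fit, path)
        back = pm.load_model(path)
        probe = np.linspace(values.min(), values.max(), 17)
        np.testing.assert_allclose(np.asarray(back.cdf(probe)),
                                   np.asarray(fit.cdf(probe)), atol=1e-12)
        np.testing.assert_array_equal(back.sample(5, seed=3),
                                      fit.sample(5, seed=3))
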