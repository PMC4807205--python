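import itertools

import numpy as np
import pytest

import growthmap as gm
from growthmap.fit import GridConfig, r_squared, rescale_fitted


def small_logistic_target(k=1.5, x0=0.01, n=60, seed=7):
    params = gm.MapParameters("logistic", x0=x0, k=k, n_steps=n)
    # narrow frame keeps every cumulative level positive (no truncation)
    spec = gm.SyntheticSpec(params, scale_sd=50.0, seed=seed)
    series, _ = gm.generate_series(spec)
    return gm.build_cumulative(series)


class TestRSquared:
    def test_perfect_prediction(self, italy_target):
        ts = gm.standardize(italy_target.values).z_values
        assert r_squared(ts, ts) == pytest.approx(1.0)

    def test_mean_predictor_scores_zero(self, italy_target):
        ts = gm.standardize(italy_target.values).z_values
        assert r_squared(ts, np.zeros_like(ts)) == pytest.approx(0.0)

    def test_worse_than_mean_goes_negative_unclamped(self, italy_target):
        ts = gm.standardize(italy_target.values).z_values
        assert r_squared(ts, -ts) == pytest.approx(-3.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            r_squared([0.0, 1.0, -1.0], [0.0, 1.0])

    def test_noncentered_target_rejected(self):
        with pytest.raises(ValueError, match="mean 0"):
            r_squared([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])


class TestRescaleFitted:
    def test_identity_frame(self):
        orbit = np.array([0.1, 0.2, 0.4])
        out = rescale_fitted(orbit, orbit.mean(), orbit.std(),
                             orbit.mean(), orbit.std())
        assert np.allclose(out, orbit)

    def test_moments_mapped_to_target_frame(self):
        orbit = np.linspace(0.001, 0.08, 50)
        out = rescale_fitted(orbit, 427.75, 252.88, orbit.mean(), orbit.std())
        assert out.mean() == pytest.approx(427.75)
        assert out.std() == pytest.approx(252.88)

    def test_zero_orbit_sd_rejected(self):
        with pytest.raises(ValueError, match="orbit_sd"):
            rescale_fitted([0.1, 0.1], 0.0, 1.0, 0.1, 0.0)


class TestFitLogistic:
    def test_short_target_rejected(self):
        s = gm.AnnualRateSeries([1900, 1901, 1902], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="observations"):
            gm.fit_logistic(gm.build_cumulative(s))

    def test_constant_target_rejected(self):
        s = gm.AnnualRateSeries(np.arange(1900, 1915),
                                [1.0] + [0.0] * 14)
        with pytest.raises(ValueError, match="zero variance"):
            gm.fit_logistic(gm.build_cumulative(s))

    def test_noiseless_on_grid_truth_recovered_exactly(self):
        target = small_logistic_target(k=1.5, x0=0.01, n=136)
        fit = gm.fit_logistic(target)
        assert fit.r2 > 0.9999
        assert abs(fit.params.k - 1.5) <= 5e-5
        assert abs(fit.params.x0 - 0.01) <= 5e-6

    def test_result_consistency_invariants(self, italy_target,
                                           italy_logistic_fit):
        fit = italy_logistic_fit
        # stored r2 equals the Step-4 formula recomputed from stored series
        ts = gm.standardize(italy_target.values).z_values
        tp = gm.standardize(fit.orbit_series()).z_values
        assert fit.r2 == pytest.approx(r_squared(ts, tp), abs=1e-12)
        # fitted values re-derivable from the stored parameters and moments
        assert np.allclose(fit.recompute_fitted(), fit.fitted_values,
                           atol=1e-12)
        assert np.allclose(np.diff(fit.fitted_values),
                           fit.fitted_derivatives, atol=1e-12)

    def test_winner_beats_every_coarse_candidate(self):
        target = small_logistic_target(n=40)
        config = GridConfig(k_step=0.1, x0_step=0.01, refinements=0)
        fit = gm.fit_logistic(target, config)
        for k in np.arange(0.1, 4.01, 0.1):
            score = gm.score_candidate(
                target, gm.MapParameters("logistic", x0=fit.params.x0, k=k,
                                         n_steps=target.n_obs))
            assert score <= fit.r2 + 1e-12

    def test_coarse_grid_matches_brute_force_oracle(self):
        """The vectorized scanner's argmax equals naive enumeration, exactly."""
        target = small_logistic_target(n=50)
        config = GridConfig(k_step=0.05, x0_step=0.005, refinements=0)
        fit = gm.fit_logistic(target, config)
        best = (-np.inf, None, None)
        for k in np.arange(0.0, 4.0 + 1e-9, 0.05):
            for x0 in np.arange(0.005, 0.2 + 1e-9, 0.005):
                try:
                    s = gm.score_candidate(
                        target, gm.MapParameters("logistic", x0=x0, k=k,
                                                 n_steps=target.n_obs))
                except ValueError:
                    continue
                if s > best[0]:
                    best = (s, k, x0)
        assert fit.params.k == pytest.approx(best[1], abs=1e-12)
        assert fit.params.x0 == pytest.approx(best[2], abs=1e-12)
        assert fit.r2 == pytest.approx(best[0], abs=1e-9)

    def test_refinement_never_decreases_best_score(self, italy_target):
        coarse = gm.fit_logistic(italy_target, GridConfig(refinements=0))
        refined = gm.fit_logistic(italy_target, GridConfig(refinements=2))
        assert refined.r2 >= coarse.r2 - 1e-15
        bests = [p["best"]["r2"] for p in refined.search_log["passes"]]
        assert all(b2 >= b1 - 1e-15 for b1, b2 in zip(bests, bests[1:]))

    def test_search_log_records_counts(self, italy_logistic_fit):
        log = italy_logistic_fit.search_log
        assert log["n_candidates"] > 300_000
        assert log["family"] == "logistic"
        assert len(log["passes"]) == 3


class TestFitCubic:
    def test_quadratic_subfamily_matches_logistic_fit(self, italy_target):
        config = GridConfig(k_step=0.02, x0_step=0.002, refinements=1)
        lo = gm.fit_logistic(italy_target, config)
        cu = gm.fit_cubic(italy_target, config, quadratic_only=True)
        k1, k2, k3 = cu.params.poly_coeffs
        assert k1 == pytest.approx(lo.params.k, abs=1e-12)
        assert k2 == pytest.approx(lo.params.k, abs=1e-12)
        assert k3 == 0.0
        assert cu.params.x0 == pytest.approx(lo.params.x0, abs=1e-12)
        assert cu.r2 == pytest.approx(lo.r2, abs=1e-10)

    def test_synthetic_cubic_coefficients_recovered(self):
        truth = gm.MapParameters("cubic", x0=0.003,
                                 poly_coeffs=(1.07, 1.7, 12.0), n_steps=136)
        series, _ = gm.generate_series(gm.SyntheticSpec(truth, seed=3))
        target = gm.build_cumulative(series)
        config = GridConfig(k1_range=(1.0, 1.15), k1_step=0.01,
                            k2_range=(0.0, 3.0), k2_step=0.1,
                            k3_range=(0.0, 20.0), k3_step=1.0,
                            cubic_x0_range=(0.0, 0.01), cubic_x0_step=0.0005,
                            refinements=2)
        fit = gm.fit_cubic(target, config)
        k1, k2, k3 = fit.params.poly_coeffs
        assert fit.r2 > 0.9999
        assert k1 == pytest.approx(1.07, abs=1e-4)
        assert k2 == pytest.approx(1.7, abs=1e-2)
        assert k3 == pytest.approx(12.0, abs=1e-1)

    def test_divergent_candidates_are_counted_not_fatal(self, italy_target):
        config = GridConfig(k1_range=(1.0, 1.1), k1_step=0.05,
                            k2_range=(0.0, 1.0), k2_step=0.5,
                            k3_range=(0.0, 400.0), k3_step=100.0,
                            cubic_x0_range=(0.0, 0.05), cubic_x0_step=0.01,
                            refinements=0)
        fit = gm.fit_cubic(italy_target, config)
        assert fit.search_log["n_divergent"] > 0
        assert np.isfinite(fit.r2)


class TestComparisonFits:
    def test_linear_interpolates_exact_line(self):
        s = gm.AnnualRateSeries(np.arange(1900, 1912), [5.0] + [2.0] * 11)
        fit = gm.fit_linear_trend(gm.build_cumulative(s))
        assert fit.slope == pytest.approx(2.0)
        assert fit.r2 == pytest.approx(1.0)

    def test_linear_constant_input_has_zero_r2(self):
        s = gm.AnnualRateSeries(np.arange(1900, 1910), [3.0] + [0.0] * 9)
        fit = gm.fit_linear_trend(gm.build_cumulative(s))
        assert fit.slope == 0.0
        assert fit.r2 == 0.0

    def test_exponential_log_linear_identity(self):
        years = np.arange(1900, 1940)
        t = np.arange(40.0)
        levels = 10.0 * np.exp(0.05 * t)
        rates = np.diff(np.concatenate([[0.0], levels]))
        s = gm.AnnualRateSeries(years, rates)
        fit = gm.fit_exponential(gm.build_cumulative(s))
        assert fit.a == pytest.approx(0.05, abs=1e-12)
        assert fit.r2 == pytest.approx(1.0)
        assert fit.base == pytest.approx(np.exp(0.05))

    def test_exponential_rejects_nonpositive_values(self):
        s = gm.AnnualRateSeries(np.arange(1900, 1910), [0.0] + [1.0] * 9)
        with pytest.raises(ValueError, match="positive"):
            gm.fit_exponential(gm.build_cumulative(s))


class TestDerivativeFitR2:
    def test_exact_cumulative_scores_one(self, italy_series, italy_target):
        score = gm.derivative_fit_r2(italy_series, italy_target.values,
                                     italy_target.years)
        assert score == pytest.approx(1.0)

    def test_alignment_mismatch_rejected(self, italy_series, italy_target):
        with pytest.raises(ValueError):
            gm.derivative_fit_r2(italy_series, italy_target.values[:-1],
                                 italy_target.years)

    def test_constant_derivative_has_no_explanatory_power(
            self, italy_series, italy_target):
        lin = gm.fit_linear_trend(italy_target)
        score = gm.derivative_fit_r2(italy_series, lin.fitted_values,
                                     italy_target.years)
        assert abs(score) < 0.1
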