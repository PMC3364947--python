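"""Growth-model fitting: noiseless identities, posterior behavior, rate ratios."""

import numpy as np
import pytest

from rholandscape.growth import (
    GrowthCurve,
    effective_growth_rate,
    exp_window_rate,
    fit_growth_model,
    fit_growth_spline,
    growth_rate_ratio,
    lag_and_saturation,
    sample_posterior,
    significantly_different,
)
from rholandscape.synthetic import GrowthParams, simulate_growth_curves


class TestModelFit:
    def test_noiseless_recovery_is_exact(self, clean_curve):
        curve, p = clean_curve
        fit = fit_growth_model(curve)
        assert abs(fit.gamma - p.gamma) < 1e-4
        assert abs(fit.lag - p.lag) < 0.01

    def test_flat_curve_reports_no_growth(self):
        t = np.linspace(0, 16, 97)
        curve = GrowthCurve("flat", t, np.full_like(t, 0.05), blank=0.04)
        fit = fit_growth_model(curve)
        assert fit.no_growth and fit.gamma == 0.0

    def test_decreasing_curve_reports_no_growth(self):
        t = np.linspace(0, 16, 97)
        curve = GrowthCurve("down", t, 0.5 - 0.02 * t, blank=0.04)
        fit = fit_growth_model(curve)
        assert fit.no_growth and fit.gamma == 0.0

    def test_too_few_points_rejected(self):
        t = np.linspace(0, 1, 5)
        with pytest.raises(Exception):
            fit_growth_model(GrowthCurve("short", t, 0.1 + 0.1 * t, blank=0.04))

    def test_rate_equals_inverse_doubling_time(self):
        # a doubling time of 2 h must yield gamma = 0.5 on noiseless input
        p = GrowthParams(gamma=0.5, lag=1.0, amplitude=6.0, baseline=-6.6)
        c = simulate_growth_curves(p, n_replicates=1, noise_sd=0.0, seed=0)[0]
        assert abs(fit_growth_model(c).gamma - 0.5) < 1e-4

    def test_mean_recovery_under_noise(self):
        gammas = []
        for i in range(60):
            c = simulate_growth_curves(
                GrowthParams(0.5, 2.0, 6.0, -6.6), n_replicates=1, noise_sd=0.005, seed=100 + i
            )[0]
            gammas.append(fit_growth_model(c).gamma)
        assert abs(np.mean(gammas) - 0.5) / 0.5 < 0.05


class TestPosterior:
    def test_fixed_seed_reproducible(self, clean_curve):
        curve, _ = clean_curve
        fit = fit_growth_model(curve)
        a = sample_posterior(fit, n=500, seed=42).gamma_samples.copy()
        b = sample_posterior(fit, n=500, seed=42).gamma_samples
        np.testing.assert_array_equal(a, b)

    def test_near_zero_covariance_collapses_to_point(self, clean_curve):
        curve, p = clean_curve
        fit = fit_growth_model(curve)
        sample_posterior(fit, n=200, seed=0)
        assert np.all(np.abs(fit.gamma_samples - p.gamma) < 1e-3)

    def test_requested_sample_count(self, clean_curve):
        curve, _ = clean_curve
        fit = sample_posterior(fit_growth_model(curve), n=10_000, seed=0)
        assert fit.posterior_samples.shape == (10_000, 4)

    def test_ci_matches_normal_quantiles(self):
        # oracle: for a pure normal gamma posterior the 95% CI is mu +/- 1.96 sd
        rng = np.random.default_rng(0)
        fit_samples = rng.normal(1.0, 0.05, 200_000)
        lo, hi = np.percentile(fit_samples, [2.5, 97.5])
        assert abs(lo - (1.0 - 1.96 * 0.05)) < 0.002
        assert abs(hi - (1.0 + 1.96 * 0.05)) < 0.002


class TestEffectiveRate:
    def test_exact_on_noiseless_exponential(self):
        t = np.linspace(0, 10, 61)
        od = 0.04 + 0.01 * 2.0 ** (0.094 * t)
        fit = effective_growth_rate(GrowthCurve("w", t, od, blank=0.04), (0.0, 10.0))
        assert abs(fit.gamma - 0.094) < 1e-9

    def test_flat_window_rate_near_zero(self):
        t = np.linspace(0, 10, 61)
        od = np.full_like(t, 0.5)
        fit = effective_growth_rate(GrowthCurve("w", t, od, blank=0.04), (2.0, 8.0))
        assert abs(fit.gamma) < 1e-9

    def test_window_with_too_few_points_rejected(self):
        t = np.linspace(0, 10, 61)
        with pytest.raises(ValueError):
            effective_growth_rate(GrowthCurve("w", t, t + 1, blank=0.0), (0.0, 0.3))

    def test_bootstrap_ci_matches_analytic_slope_ci(self):
        rng = np.random.default_rng(1)
        t = np.linspace(0, 10, 61)
        od = 0.04 + 0.05 * 2.0 ** (0.3 * t) * 2.0 ** rng.normal(0, 0.02, t.shape)
        curve = GrowthCurve("w", t, od, blank=0.04)
        fit = effective_growth_rate(curve, (0.0, 10.0), n_samples=100_000, seed=2)
        lo, hi = np.percentile(fit.gamma_samples, [2.5, 97.5])
        from scipy import stats

        res = stats.linregress(t, curve.log2_od())
        half = 1.96 * res.stderr
        assert abs((hi - lo) / 2 - half) < 0.15 * half


class TestExpWindowRate:
    def test_single_curve_matches_simple_regression(self):
        t = np.linspace(0, 5, 31)
        od = 0.04 + 0.01 * 2.0 ** (0.8 * t)
        c = GrowthCurve("w", t, od, blank=0.04)
        pooled = exp_window_rate([c], doubling_cutoff=3)
        from scipy import stats

        v = c.od - c.blank
        mask = v <= v[0] * 8
        ref = stats.linregress(t[mask], np.log2(v[mask])).slope
        assert abs(pooled.gamma - ref) < 1e-10

    def test_shifted_intercepts_share_exact_slope(self):
        t = np.linspace(0, 5, 31)
        curves = [
            GrowthCurve(f"w{i}", t, 0.04 + (0.01 * 2**i) * 2.0 ** (0.6 * t), blank=0.04)
            for i in range(3)
        ]
        fit = exp_window_rate(curves, doubling_cutoff=3)
        assert abs(fit.gamma - 0.6) < 1e-8

    def test_balanced_pooling_equals_mean_of_per_well_slopes(self):
        rng = np.random.default_rng(7)
        t = np.linspace(0, 4, 25)
        slopes = []
        curves = []
        from scipy import stats

        for i in range(4):
            y = -6.0 + 0.5 * t + rng.normal(0, 0.01, t.shape)
            od = 0.04 + 2.0**y
            c = GrowthCurve(f"w{i}", t, od, blank=0.04)
            curves.append(c)
            slopes.append(stats.linregress(t, np.log2(od - 0.04)).slope)
        fit = exp_window_rate(curves, doubling_cutoff=100)  # keep all points: balanced
        assert abs(fit.gamma - np.mean(slopes)) < 1e-8

    def test_no_points_below_cutoff_rejected(self):
        t = np.linspace(0, 5, 31)
        c = GrowthCurve("w", t, np.zeros_like(t), blank=0.04)
        with pytest.raises(Exception):
            exp_window_rate([c])


class TestLagSaturation:
    def test_closed_form_on_noiseless_logistic(self):
        p = GrowthParams(gamma=1.0, lag=2.0, amplitude=6.0, baseline=-6.6)
        c = simulate_growth_curves(p, n_replicates=1, noise_sd=0.0, seed=0)[0]
        lag, tsat = lag_and_saturation(c)
        k = 4 * p.gamma / p.amplitude
        tm = p.lag + 2 / k
        assert abs(lag - 2.0) < 0.01
        assert abs(tsat - (tm + np.log(19) / k)) < 0.05

    def test_no_growth_gives_missing_values(self):
        t = np.linspace(0, 16, 97)
        lag, tsat = lag_and_saturation(GrowthCurve("f", t, np.full_like(t, 0.05), blank=0.04))
        assert np.isnan(lag) and np.isnan(tsat)

    def test_saturation_time_decreases_with_rate(self):
        tsats = []
        for g in [0.4, 0.8, 1.6]:
            p = GrowthParams(gamma=g, lag=2.0, amplitude=6.0, baseline=-6.6)
            c = simulate_growth_curves(p, n_replicates=1, noise_sd=0.0, seed=0)[0]
            tsats.append(lag_and_saturation(c)[1])
        assert tsats[0] > tsats[1] > tsats[2]


class TestRateRatio:
    def test_identical_samples_give_unit_ratio(self):
        s = np.random.default_rng(0).normal(1.0, 0.05, 5000)
        r = growth_rate_ratio(s, s)
        assert r.gamma_ratio == pytest.approx(1.0)
        assert r.ci_low <= 1.0 <= r.ci_high

    def test_degenerate_point_estimates(self):
        # ratio of two published-scale point rates, 4 decimal places
        a = np.full(1000, 1.079)
        b = np.full(1000, 1.017)
        r = growth_rate_ratio(a, b)
        assert round(r.gamma_ratio, 4) == 1.0610

    def test_scale_invariance(self):
        rng = np.random.default_rng(3)
        a = rng.normal(1.0, 0.03, 4000)
        b = rng.normal(0.9, 0.03, 4000)
        r1 = growth_rate_ratio(a, b)
        r2 = growth_rate_ratio(5 * a, 5 * b)
        assert r1.gamma_ratio == pytest.approx(r2.gamma_ratio)
        assert r1.ci_low == pytest.approx(r2.ci_low)
        assert r1.ci_high == pytest.approx(r2.ci_high)

    def test_nonpositive_denominator_draws_flagged(self):
        a = np.ones(100)
        b = np.concatenate([np.ones(99), [0.0]])
        r = growth_rate_ratio(a, b)
        assert "nonpositive_denominator_draws_dropped" in r.flags

    def test_non_overlapping_cis_are_significant(self):
        rng = np.random.default_rng(4)
        base = growth_rate_ratio(rng.normal(1.0, 0.01, 4000), rng.normal(1.0, 0.01, 4000))
        high = growth_rate_ratio(rng.normal(1.3, 0.01, 4000), rng.normal(1.0, 0.01, 4000))
        assert significantly_different(base, high)
        assert not significantly_different(base, base)


def test_spline_rate_agrees_with_model_on_clean_logistic(clean_curve):
    curve, p = clean_curve
    fit = fit_growth_spline(curve)
    assert abs(fit.gamma - p.gamma) / p.gamma < 0.02
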