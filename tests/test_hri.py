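"""Curve fits, LOESS, asymptote, loss equations, correlation summaries."""

import numpy as np
import pytest

from hriquant.hri import (ancova, asymptotic_ka, compare_fits, estimate_fhri,
                          fit_curvilinear, fit_linear, fraction_lost,
                          loess_predict, spearman_rho)

X45 = np.linspace(0.05, 9.0, 45)


class TestLinearFit:
    def test_exact_line(self):
        fit = fit_linear([0, 1, 2, 3], [1, 3, 5, 7])
        assert fit.a == pytest.approx(1.0)
        assert fit.b == pytest.approx(2.0)
        assert fit.r2 == pytest.approx(1.0)

    def test_under_minimum_points(self):
        with pytest.raises(ValueError):
            fit_linear([0, 1], [0, 1])

    def test_degenerate_x(self):
        with pytest.raises(ValueError):
            fit_linear([2, 2, 2], [1, 2, 3])

    def test_noiseless_shallow_slope_recovered_to_6_decimals(self):
        y = 0.0057 + 0.0018 * X45
        fit = fit_linear(X45, y)
        assert fit.a == pytest.approx(0.0057, abs=1e-6)
        assert fit.b == pytest.approx(0.0018, abs=1e-6)


class TestCurvilinearFit:
    def test_noiseless_recovery_to_4_significant_digits(self):
        a, b, c = 0.0126, -0.0186, 2.1237
        y = a + b * np.exp(-c * X45)
        fit = fit_curvilinear(X45, y)
        assert fit.a == pytest.approx(a, rel=1e-4)
        assert fit.b == pytest.approx(b, rel=1e-4)
        assert fit.c == pytest.approx(c, rel=1e-4)

    def test_nests_linear_in_small_c_limit(self):
        rng = np.random.default_rng(11)
        y = 0.002 + 0.0005 * X45 + rng.normal(0, 0.0004, len(X45))
        lin = fit_linear(X45, y)
        cur = fit_curvilinear(X45, y)
        # the linear model sits on the open c -> 0 boundary of the
        # curvilinear family; the fit approaches it to float conditioning
        assert cur.rss <= lin.rss * (1 + 1e-4)

    def test_flat_data_flags_unidentifiable_c(self):
        y = np.full_like(X45, 0.01)
        fit = fit_curvilinear(X45, y)
        assert fit.flagged
        assert fit.a == pytest.approx(0.01, abs=1e-9)

    def test_asymptote_is_a(self):
        fit = fit_curvilinear(X45, 0.01 - 0.008 * np.exp(-1.5 * X45))
        assert fit.predict(1e6) == pytest.approx(fit.a)


class TestModelComparison:
    def test_identical_fits(self):
        y = 1.0 + 2.0 * X45
        lin = fit_linear(X45, y)
        cur = fit_curvilinear(X45, y)
        F, p, _ = compare_fits(lin, cur)
        assert F == pytest.approx(0.0, abs=1e-6)
        assert p == pytest.approx(1.0, abs=1e-6)

    def test_strong_curvature_detected(self, rng):
        # effect sizes like the genome-wide recombination analysis
        a, b, c = 0.0126, -0.0186, 2.1237
        y = a + b * np.exp(-c * X45) + rng.normal(0, 0.0012, len(X45))
        F, p, daic = compare_fits(fit_linear(X45, y), fit_curvilinear(X45, y))
        assert p < 0.001
        assert daic > 0

    def test_aic_and_f_concordant(self, rng):
        """delta AIC > 0 iff F exceeds its AIC-equivalent cutoff
        (n-3)(e^{2/n} - 1); agreement on noisy linear-truth data."""
        n = len(X45)
        cutoff = (n - 3) * (np.exp(2.0 / n) - 1.0)
        agree = 0
        trials = 300
        for _ in range(trials):
            y = 0.005 + 0.001 * X45 + rng.normal(0, 0.002, n)
            cur = fit_curvilinear(X45, y, starts=(1e-6, 0.5, 2.0))
            F, p, daic = compare_fits(fit_linear(X45, y), cur)
            agree += (daic > 0) == (F > cutoff)
        assert agree / trials >= 0.95


class TestLoess:
    def test_constant_and_quadratic_exactness(self):
        x = np.linspace(0, 10, 20)
        assert loess_predict(x, np.full(20, 3.0)) == pytest.approx(np.full(20, 3.0))
        y = 1.0 - 0.5 * x + 0.02 * x ** 2
        assert loess_predict(x, y, span=1.0) == pytest.approx(y, abs=1e-9)

    def test_agrees_with_weighted_least_squares_oracle(self):
        rng = np.random.default_rng(5)
        x = np.sort(rng.uniform(0, 8, 30))
        y = np.sin(x) + rng.normal(0, 0.1, 30)
        span = 0.8
        q = int(np.ceil(span * len(x)))
        for x0 in (1.0, 4.0, 7.0):
            d = np.abs(x - x0)
            idx = np.argsort(d, kind="stable")[:q]
            w = (1 - (d[idx] / d[idx].max()) ** 3) ** 3
            X = np.vander(x[idx] - x0, 3, increasing=True)
            beta = np.linalg.solve(X.T @ (w[:, None] * X), X.T @ (w * y[idx]))
            got = loess_predict(x, y, span=span, query=[x0])[0]
            assert got == pytest.approx(beta[0], abs=1e-6)

    def test_span_validation_and_minimum_points(self):
        x = np.arange(10.0)
        with pytest.raises(ValueError):
            loess_predict(x, x, span=0.0)
        with pytest.raises(ValueError):
            loess_predict(x[:4], x[:4])


class TestAsymptote:
    def test_mean_of_eligible_bins(self):
        bins = [(1.5, 0.002), (3.0, 0.01), (4.0, 0.012)]
        assert asymptotic_ka(bins, 2.0) == pytest.approx(0.011)

    def test_equal_values_above_threshold(self):
        assert asymptotic_ka([(3.0, 0.007), (6.0, 0.007)], 2.0) == 0.007

    def test_no_bin_above_threshold_errors(self):
        with pytest.raises(ValueError, match="threshold"):
            asymptotic_ka([(1.0, 0.01), (4.9, 0.02)], 5.0)


class TestLossEquations:
    def test_zero_loss_when_curve_sits_on_asymptote(self):
        res = estimate_fhri([0.5, 1.5, 3.0], [100, 100, 100],
                            [0.01, 0.01, 0.01], 0.01)
        assert res.f_hri == 0.0

    def test_three_bin_hand_computation_with_and_without_clamp(self):
        rr = [0.5, 1.0, 3.0]
        la = [100.0, 200.0, 300.0]
        preds = [-0.002, 0.004, 0.01]
        ka_no = 0.01
        res = estimate_fhri(rr, la, preds, ka_no, clamp=False)
        assert res.total_no_hri == pytest.approx(6.0)
        assert res.total_lost == pytest.approx(100 * 0.012 + 200 * 0.006)
        assert res.f_hri == pytest.approx(2.4 / 6.0)
        resc = estimate_fhri(rr, la, preds, ka_no, clamp=True)
        assert resc.clamped
        assert resc.total_lost == pytest.approx(100 * 0.01 + 200 * 0.006)
        assert resc.f_hri == pytest.approx(2.2 / 6.0)

    def test_identity_holds_to_machine_precision(self, rng):
        for _ in range(50):
            n = 12
            rr = np.sort(rng.uniform(0, 8, n))
            la = rng.uniform(50, 500, n)
            preds = rng.normal(0.008, 0.004, n)
            clamp = bool(rng.integers(2))
            res = estimate_fhri(rr, la, preds, 0.01, clamp=clamp)
            assert res.f_hri == res.total_lost / res.total_no_hri
            if clamp:
                assert res.f_hri <= 1.0
                if np.all(res.per_bin_predictions[rr < 2.0] <= 0.01):
                    assert res.f_hri >= 0.0

    def test_fraction_lost_requires_positive_total(self):
        with pytest.raises(ValueError):
            fraction_lost(0.0, 1.0)


class TestSpearman:
    def test_perfect_orders(self):
        x = np.arange(10.0)
        assert spearman_rho(x, x)[0] == pytest.approx(1.0)
        assert spearman_rho(x, -x)[0] == pytest.approx(-1.0)

    def test_matches_bruteforce_rank_computation(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=10)
        y = rng.normal(size=10)
        rho, _ = spearman_rho(x, y)
        rx = np.argsort(np.argsort(x)) + 1.0
        ry = np.argsort(np.argsort(y)) + 1.0
        want = np.corrcoef(rx, ry)[0, 1]
        assert rho == pytest.approx(want, abs=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            spearman_rho([1, 1, 1, 1], [1, 2, 3, 4])


class TestAncova:
    def test_identical_groups_nothing_significant(self):
        x = np.tile(np.arange(10.0), 2)
        y = 2.0 + 0.5 * x + np.concatenate([np.zeros(10), np.zeros(10)])
        # add tiny symmetric jitter so the design is non-singular
        rng = np.random.default_rng(0)
        noise = rng.normal(0, 0.01, 10)
        y = y + np.concatenate([noise, noise])
        out = ancova(y, x, ["a"] * 10 + ["b"] * 10)
        assert out["intercept_p"] > 0.9
        assert out["slope_p"] > 0.9

    def test_offset_groups_move_intercept_only(self, rng):
        x = np.tile(np.arange(12.0), 2)
        noise = rng.normal(0, 0.05, 12)
        ya = 1.0 + 0.5 * x[:12] + noise
        yb = 3.0 + 0.5 * x[:12] + noise
        out = ancova(np.concatenate([ya, yb]), x, ["a"] * 12 + ["b"] * 12)
        assert out["intercept_p"] < 1e-6
        assert out["slope_p"] > 0.5
        assert out["common_slope"] == pytest.approx(0.5, abs=0.02)

    def test_heterogeneous_slopes_detected_with_power(self):
        detected = 0
        for s in range(20):
            rng = np.random.default_rng(100 + s)
            x = np.tile(np.arange(15.0), 2)
            ya = 1.0 + 0.2 * x[:15] + rng.normal(0, 0.3, 15)
            yb = 1.0 + 0.8 * x[:15] + rng.normal(0, 0.3, 15)
            out = ancova(np.concatenate([ya, yb]), x, ["a"] * 15 + ["b"] * 15)
            detected += out["slope_p"] < 0.05
        assert detected >= 19  # power > 0.9 at this effect size

    def test_validation(self):
        with pytest.raises(ValueError):
            ancova([1, 2, 3], [1, 2, 3], ["a", "a", "a"])
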