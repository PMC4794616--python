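"""Expected spectra, demography and gamma-DFE fits, alpha derivation."""

import numpy as np
import pytest

import hriquant as hq
from hriquant.counts import FoldedSFS
from hriquant.dfe import (Demography, GammaDFE, SelectionGrid,
                          estimate_alpha_ka_plus, fit_gamma_dfe,
                          fit_neutral_demography, fixation_factor,
                          relative_fixation_rate)


class TestExpectedSFS:
    def test_neutral_constant_n4_matches_one_over_i_law(self, engine128):
        """Folded neutral proportions at n=4: (1 + 1/3, 1/2) / (11/6)."""
        props = engine128.expected_folded_sfs(0.0, 1.0, 0.0, n_sample=4)
        assert props == pytest.approx([8 / 11, 3 / 11], abs=5e-3)

    def test_strong_negative_selection_concentrates_singletons(self, engine128):
        neu = engine128.expected_folded_sfs(0.0, 1.0, 0.0, n_sample=16)
        sel = engine128.expected_folded_sfs(-400.0, 1.0, 0.0, n_sample=16)
        assert sel[0] > neu[0]
        assert sel[-1] < neu[-1]

    def test_size_ratio_irrelevant_when_t2_zero(self, engine128):
        a = engine128.expected_folded_sfs(0.0, 1.0, 0.0, n_sample=16)
        b = engine128.expected_folded_sfs(0.0, 3.0, 0.0, n_sample=16)
        assert np.array_equal(a, b)

    def test_proportions_sum_to_one(self, engine128):
        for S in (0.0, -5.0, -100.0):
            p = engine128.expected_folded_sfs(S, 1.5, 0.1, n_sample=32)
            assert p.sum() == pytest.approx(1.0)
            assert np.all(p >= 0)

    def test_folding_matches_manual_fold_of_population_sampling(self, engine128):
        """Oracle: fold the unfolded binomial-sampled expectation directly."""
        from scipy.stats import binom
        n = 16
        u, n_hap = engine128.population_occupancy(-2.0, 1.5, 0.1)
        p = np.arange(1, n_hap) / n_hap
        s = np.array([np.sum(u * binom.pmf(k, n, p)) for k in range(1, n)])
        folded = np.array([s[k - 1] + (s[n - k - 1] if k != n - k else 0.0)
                           for k in range(1, n // 2 + 1)])
        got = engine128.expected_folded_sfs(-2.0, 1.5, 0.1, n_sample=n,
                                            normalize=False)
        assert got == pytest.approx(folded, rel=1e-9)

    def test_sample_larger_than_grid_rejected(self, engine128):
        with pytest.raises(ValueError):
            engine128.expected_folded_sfs(0.0, 1.0, 0.0, n_sample=256)

    def test_expansion_excess_of_rare_variants(self, engine128):
        neu = engine128.expected_folded_sfs(0.0, 1.0, 0.0, n_sample=32)
        exp = engine128.expected_folded_sfs(0.0, 2.0, 0.2, n_sample=32)
        assert exp[0] > neu[0]


class TestFixationRate:
    def test_neutral_limit_and_series(self):
        assert relative_fixation_rate(0.0) == 1.0
        for S in (1e-6, -1e-6, 1e-4, -1e-4):
            # r(S) ~ 1 + S/2 near zero
            assert relative_fixation_rate(S) == pytest.approx(1 + S / 2, abs=1e-7)

    def test_strongly_deleterious_goes_to_zero(self):
        assert relative_fixation_rate(-50.0) < 1e-19
        assert relative_fixation_rate(-1e4) == 0.0

    def test_monotone_in_S(self):
        S = np.linspace(-30, 5, 200)
        r = relative_fixation_rate(S)
        assert np.all(np.diff(r) > 0)

    def test_fixation_factor_pure_neutral_dfe(self):
        grid = SelectionGrid()
        assert fixation_factor(GammaDFE(0.0, 0.3), grid) == 1.0

    def test_fixation_factor_decreases_with_mean_strength(self):
        grid = SelectionGrid()
        vals = [fixation_factor(GammaDFE(m, 0.3), grid)
                for m in (1.0, 10.0, 100.0, 1000.0)]
        assert np.all(np.diff(vals) < 0)


class TestDemographyFit:
    def test_expected_neutral_input_recovers_generator(self, engine128):
        """Self-consistency: likelihood at the generating parameters is not
        beaten anywhere the optimizer looks."""
        n = 64
        truth = (1.5, 0.2)
        props = engine128.expected_folded_sfs(0.0, *truth, n_sample=n)
        counts = np.round(props * 1e6).astype(int)
        demog, ll = fit_neutral_demography(FoldedSFS(n, counts), engine128)
        from hriquant.dfe import _multinomial_loglik
        ll_truth = _multinomial_loglik(
            counts, engine128.expected_folded_sfs(0.0, *truth, n_sample=n))
        assert ll >= ll_truth - 1e-6
        assert demog.size_ratio == pytest.approx(1.5, abs=0.25)
        assert demog.t2 == pytest.approx(0.2, abs=0.1)

    def test_constant_size_recovered_as_constant(self, engine128):
        n = 64
        props = engine128.expected_folded_sfs(0.0, 1.0, 0.0, n_sample=n)
        counts = np.round(props * 1e6).astype(int)
        demog, _ = fit_neutral_demography(FoldedSFS(n, counts), engine128)
        assert demog.size_ratio == 1.0 and demog.t2 == 0.0

    def test_monomorphic_input_rejected(self, engine128):
        with pytest.raises(ValueError):
            fit_neutral_demography(FoldedSFS.zeros(64), engine128)


class TestGammaFit:
    def test_neutral_selected_sfs_drives_mean_to_boundary(self, engine128):
        n = 64
        props = engine128.expected_folded_sfs(0.0, 1.0, 0.0, n_sample=n)
        counts = np.round(props * 3e5).astype(int)
        dfe, _ = fit_gamma_dfe(FoldedSFS(n, counts), Demography(1.0, 0.0),
                               engine128)
        assert fixation_factor(dfe, SelectionGrid()) > 0.9

    def test_recovery_from_expected_spectrum(self, engine128, selection_grid):
        """Near-infinite-data recovery of shape and of the DFE-averaged
        fixation rate (what alpha actually consumes)."""
        n = 128
        truth = GammaDFE(2000.0, 0.3)
        demog = Demography(1.5, 0.1)
        w = selection_grid.weights(truth)
        mix = np.zeros(n // 2)
        for wj, S in zip(w, selection_grid.S):
            if wj > 0:
                mix += wj * engine128.expected_folded_sfs(
                    S, demog.size_ratio, demog.t2, n_sample=n, normalize=False)
        counts = np.round(mix / mix.sum() * 1e6).astype(int)
        dfe, _ = fit_gamma_dfe(FoldedSFS(n, counts), demog, engine128,
                               selection_grid)
        assert dfe.shape_beta == pytest.approx(0.3, abs=0.1)
        er_true = fixation_factor(truth, selection_grid)
        er_est = fixation_factor(dfe, selection_grid)
        assert er_est == pytest.approx(er_true, rel=0.15)


class TestAlphaDerivation:
    def test_alpha_zero_when_expectation_equals_observation(self):
        # choose the fixation factor so that d_exp = ka exactly
        fit = estimate_alpha_ka_plus(None, None, D0=100, L0=10_000, D4=0,
                                     L4=1000, gc4=0.5, P4_ts=0.0, P4_tv=0.0,
                                     fixation=1.0)
        # with zero 4-fold divergence k4=0 so d_exp=0; use a direct pair
        ka = fit.ka
        fit0 = estimate_alpha_ka_plus(None, None, D0=100, L0=10_000, D4=0,
                                      L4=1000, gc4=0.5,
                                      P4_ts=0.0, P4_tv=0.0, fixation=0.0)
        assert fit0.ka_plus == pytest.approx(ka)

    def test_alpha_half_construction(self):
        # pick P,Q so k4 equals ka: then fixation=0.5 gives alpha=0.5
        from hriquant.counts import jc_correct
        ka = jc_correct(0.01)
        # choose transversion-only proportion q with K2P = ka:
        # -0.5 ln(1-q) - 0.25 ln(1-2q) = ka -> solve numerically
        from scipy.optimize import brentq
        q = brentq(lambda q: -0.5 * np.log(1 - q) - 0.25 * np.log(1 - 2 * q)
                   - ka, 0, 0.4)
        fit = estimate_alpha_ka_plus(None, None, D0=100, L0=10_000, D4=1,
                                     L4=1000, gc4=0.5, P4_ts=0.0, P4_tv=q,
                                     fixation=0.5)
        assert fit.alpha == pytest.approx(0.5, rel=1e-9)
        assert fit.ka_plus == pytest.approx(0.5 * ka, rel=1e-9)
        assert fit.omega_a == pytest.approx(fit.ka_plus / fit.k4, rel=1e-12)

    def test_identity_ka_plus_equals_alpha_times_ka(self):
        fit = estimate_alpha_ka_plus(None, None, D0=150, L0=9_000, D4=500,
                                     L4=3_000, gc4=0.6, P4_ts=0.1, P4_tv=0.06,
                                     fixation=0.08)
        assert fit.ka_plus == pytest.approx(fit.alpha * fit.ka, rel=1e-12)

    def test_zero_ka_flagged(self):
        with pytest.raises(ValueError):
            estimate_alpha_ka_plus(None, None, D0=0, L0=1000, D4=10, L4=1000,
                                   gc4=0.5, P4_ts=0.01, P4_tv=0.0, fixation=0.1)
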