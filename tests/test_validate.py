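import numpy as np
import pytest

from eeglrtc.datatypes import FluctuationFunction
from eeglrtc.dfa import dfa_exponent_batch, fluctuation, make_box_grid
from eeglrtc.errors import FitError, ParameterError, SampleSizeError
from eeglrtc.synth import gen_arfima, gen_fgn
from eeglrtc.validate import (compare_arma_arfima, fit_arma, frac_diff,
                              frac_diff_weights, mldfa, r_squared_linear,
                              select_orders, surrogate_test)


class TestSurrogateTest:
    def test_long_memory_detected(self):
        rng = np.random.default_rng(0)
        wins = np.stack([gen_fgn(256, 0.8, rng) for _ in range(40)])
        rep = surrogate_test(wins, seed=1)
        assert rep.p_value < 0.001
        assert 0.45 <= np.nanmean(rep.h_shuffled) <= 0.55

    def test_shuffle_preserves_moments(self):
        rng = np.random.default_rng(2)
        w = rng.standard_normal((25, 256))
        shuf = rng.permuted(w, axis=1)
        assert np.allclose(np.sort(shuf, axis=1), np.sort(w, axis=1))

    def test_too_few_windows(self):
        with pytest.raises(SampleSizeError):
            surrogate_test(np.zeros((5, 256)))

    def test_white_noise_mostly_not_rejected(self):
        # null calibration (light): white-noise windows should usually
        # not yield tiny p-values
        rng = np.random.default_rng(3)
        rejections = 0
        for _ in range(10):
            wins = rng.standard_normal((25, 256))
            rep = surrogate_test(wins, seed=rng)
            rejections += rep.p_value < 0.01
        assert rejections <= 3


class TestFracDiff:
    def test_d_zero_identity(self, rng):
        x = rng.standard_normal(100)
        assert np.array_equal(frac_diff(x, 0.0), x)

    def test_weights_d03(self):
        w = frac_diff_weights(4, 0.3)
        assert np.allclose(w, [1.0, -0.3, -0.105, -0.0595])

    def test_removes_memory(self):
        rng = np.random.default_rng(5)
        wins = np.stack([frac_diff(gen_arfima(512, d=0.3, seed=rng), 0.3)
                         for _ in range(30)])
        h, _ = dfa_exponent_batch(wins)
        assert 0.45 <= h.mean() <= 0.55

    def test_exact_inverse_of_integration(self):
        # truncated (1-B)^d and (1-B)^{-d} are exact inverses
        x = gen_arfima(256, d=0.35, seed=7)
        eps = gen_arfima(256, d=0.0, seed=7)
        assert np.allclose(frac_diff(x, 0.35), eps, atol=1e-10)

    def test_d_bound(self):
        with pytest.raises(ParameterError):
            frac_diff(np.ones(10), 1.2)


class TestFitArma:
    def test_ar1_recovery(self):
        rng = np.random.default_rng(0)
        phis = []
        for _ in range(10):
            x = gen_arfima(256, ar_coeffs=[0.6], d=0.0, seed=rng)
            _, _, params = fit_arma(x, 1)
            phis.append(params[1])  # [const, ar1, sigma2]
        assert 0.45 <= np.median(phis) <= 0.75

    def test_loglik_nondecreasing_in_order(self):
        x = gen_arfima(512, ar_coeffs=[0.5], d=0.0, seed=3)
        ll1, _, _ = fit_arma(x, 1, method="statespace")
        ll5, _, _ = fit_arma(x, 5, method="statespace")
        assert ll5 >= ll1 - 0.1  # nested models, numerical slack

    def test_aic_parsimony(self):
        rng = np.random.default_rng(1)
        wins_aic = []
        for _ in range(20):
            x = gen_arfima(256, ar_coeffs=[0.6], d=0.0, seed=rng)
            _, a1, _ = fit_arma(x, 1)
            _, a5, _ = fit_arma(x, 5)
            wins_aic.append(a1 < a5)
        assert sum(wins_aic) > 10

    def test_zero_series_rejected(self):
        with pytest.raises(FitError):
            fit_arma(np.zeros(256), 1)

    def test_q_restricted(self):
        with pytest.raises(ParameterError):
            fit_arma(np.random.default_rng(0).standard_normal(128), 1, q=1)


class TestSelectOrders:
    def test_ar2_plurality(self):
        rng = np.random.default_rng(4)
        picks = []
        for _ in range(30):
            x = gen_arfima(512, ar_coeffs=[0.5, 0.3], d=0.0, seed=rng)
            picks.append(select_orders(x)[0])
        values, counts = np.unique(picks, return_counts=True)
        assert values[np.argmax(counts)] == 2

    def test_ar1_plurality(self):
        rng = np.random.default_rng(5)
        picks = []
        for _ in range(30):
            x = gen_arfima(512, ar_coeffs=[0.7], d=0.0, seed=rng)
            picks.append(select_orders(x)[0])
        values, counts = np.unique(picks, return_counts=True)
        assert values[np.argmax(counts)] == 1

    def test_deterministic(self):
        x = gen_arfima(256, ar_coeffs=[0.5], d=0.0, seed=9)
        assert select_orders(x) == select_orders(x)


class TestCompareArmaArfima:
    def test_long_memory_windows_prefer_arfima(self):
        rng = np.random.default_rng(6)
        wins = np.stack([gen_arfima(256, d=0.3, seed=rng)
                         for _ in range(40)])
        rep = compare_arma_arfima(wins)
        assert rep.pct_arfima_preferred > 50.0

    def test_short_memory_windows_prefer_arma(self):
        rng = np.random.default_rng(7)
        wins = np.stack([gen_arfima(256, ar_coeffs=[0.5], d=0.0, seed=rng)
                         for _ in range(40)])
        rep = compare_arma_arfima(wins)
        assert rep.pct_arfima_preferred < 50.0

    def test_d_clamped(self):
        rng = np.random.default_rng(8)
        wins = rng.standard_normal((3, 256))
        rep = compare_arma_arfima(wins, h_estimates=np.array([1.5, 0.7, -0.2]))
        assert np.all(np.abs(rep.d) <= 0.49)


class TestMldfa:
    def test_exact_power_law(self):
        sizes = make_box_grid(4096)
        fl = FluctuationFunction(sizes, 3.0 * sizes.astype(float) ** 0.7)
        rep = mldfa(fl)
        assert rep.best_by_aic == "poly1" and rep.best_by_bic == "poly1"
        assert rep.is_linear_best
        assert rep.coeffs["poly1"][0] == pytest.approx(0.7, abs=1e-6)

    def test_crossover_beats_linear(self):
        sizes = make_box_grid(4096)
        u = np.log2(sizes.astype(float))
        knee = np.median(u)
        v = np.where(u < knee, 0.5 * u, u - 0.5 * knee)
        rep = mldfa(FluctuationFunction(sizes, 2.0 ** v))
        assert not rep.is_linear_best

    def test_nested_rss_nonincreasing(self, rng):
        sizes = make_box_grid(1024)
        u = np.log2(sizes.astype(float))
        v = 0.7 * u + 0.05 * rng.standard_normal(len(u))
        rss = []
        for order in range(1, 6):
            c = np.polyfit(u, v, order)
            rss.append(float(((v - np.polyval(c, u)) ** 2).sum()))
        assert all(rss[i + 1] <= rss[i] + 1e-12 for i in range(4))

    def test_affine_rescale_invariance(self):
        rng = np.random.default_rng(10)
        fl = fluctuation(gen_fgn(256, 0.7, rng))
        rep1 = mldfa(fl)
        rep2 = mldfa(FluctuationFunction(fl.sizes, 7.5 * fl.f))
        assert rep1.best_by_aic == rep2.best_by_aic
        assert rep1.best_by_bic == rep2.best_by_bic

    def test_quad_ratio_on_constructed_quadratic(self):
        sizes = make_box_grid(4096)
        u = np.log2(sizes.astype(float))
        v = 0.02 * u ** 2 + 0.7 * u + 1.0
        rep = mldfa(FluctuationFunction(sizes, 2.0 ** v))
        assert rep.best_by_aic == "poly2"
        assert rep.quad_lin_ratio == pytest.approx(0.02 / 0.7, rel=1e-6)

    def test_too_few_points(self):
        with pytest.raises(ParameterError):
            mldfa(FluctuationFunction(np.array([10, 20, 40]),
                                      np.array([1.0, 2.0, 4.0])))


class TestRSquaredLinear:
    def test_exact_power_law(self):
        sizes = make_box_grid(1024)
        fl = FluctuationFunction(sizes, sizes.astype(float) ** 0.6)
        assert r_squared_linear(fl) == pytest.approx(1.0)

    def test_fgn_window_high_r2(self):
        rng = np.random.default_rng(11)
        r2s = [r_squared_linear(fluctuation(gen_fgn(256, 0.7, rng)))
               for _ in range(20)]
        assert np.mean(r2s) > 0.9

    def test_uncorrelated_scatter_low_r2(self, rng):
        sizes = make_box_grid(1024)
        f = 2.0 ** rng.standard_normal(len(sizes))
        assert r_squared_linear(FluctuationFunction(sizes, f)) < 0.5


class TestCascade:
    """The three stages agree on synthetic long-memory data."""

    @pytest.mark.parametrize("h_true", [0.65, 0.75])
    def test_cascade_passes_on_fgn(self, h_true):
        rng = np.random.default_rng(int(h_true * 100))
        wins = np.stack([gen_fgn(256, h_true, rng) for _ in range(30)])
        sur = surrogate_test(wins, seed=rng)
        assert sur.p_value < 0.05
        cmp_rep = compare_arma_arfima(wins)
        assert cmp_rep.pct_arfima_preferred > 50.0

    @pytest.mark.parametrize("h_true", [0.65, 0.75])
    def test_mldfa_linear_modal_on_tapered_windows(self, h_true):
        # the pipeline tapers windows before DFA; on tapered fGn windows
        # the linear model is the single most frequently selected shape
        rng = np.random.default_rng(1)
        taper = np.hanning(256)
        winners = []
        for _ in range(60):
            fl = fluctuation(gen_fgn(256, h_true, rng) * taper)
            winners.append(mldfa(fl).best_by_aic)
        values, counts = np.unique(winners, return_counts=True)
        assert values[np.argmax(counts)] == "poly1"
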