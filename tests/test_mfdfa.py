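import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fracopd.mfdfa import (
    HurstCurve,
    MfdfaConfig,
    group_hurst_band,
    hq_wasserstein,
    hurst_curve,
    multifractality_report,
    profile,
    scaling_function,
    window_fluctuation,
)
from fracopd.synthdata import cascade_hurst, gen_binomial_cascade, gen_fgn


class TestProfile:
    def test_constant_series_gives_zeros(self):
        assert np.allclose(profile(np.array([1.0, 1.0, 1.0])), 0.0)

    def test_alternating_series(self):
        assert np.allclose(profile(np.array([1.0, -1.0, 1.0, -1.0])), [1, 0, 1, 0])

    @given(st.lists(st.floats(-1e6, 1e6), min_size=2, max_size=200))
    @settings(max_examples=50, deadline=None)
    def test_last_value_telescopes_to_zero(self, xs):
        Y = profile(np.array(xs))
        assert abs(Y[-1]) < 1e-6 * max(1.0, np.max(np.abs(xs)))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            profile(np.array([]))


class TestWindowFluctuation:
    def test_linear_window_detrends_to_zero(self):
        Y = 3.0 * np.arange(20.0) + 2.0
        assert window_fluctuation(Y, 1, 10) < 1e-12

    def test_matches_hand_ols(self):
        """F for Y=[0,1,0] against an explicit least-squares line fit."""
        Y = np.array([0.0, 1.0, 0.0])
        t = np.arange(3.0)
        coef = np.polyfit(t, Y, 1)
        resid = Y - np.polyval(coef, t)
        expected = np.sqrt(np.mean(resid**2))
        assert np.isclose(window_fluctuation(Y, 1, 3), expected)

    def test_homogeneity(self):
        rng = np.random.default_rng(0)
        Y = rng.standard_normal(64)
        f1 = window_fluctuation(Y, 2, 16)
        f2 = window_fluctuation(2.0 * Y, 2, 16)
        assert np.isclose(f2, 2.0 * f1)

    def test_too_small_scale_rejected(self):
        with pytest.raises(ValueError):
            window_fluctuation(np.arange(10.0), 1, 2, detrend_order=1)


def _plain_dfa(x, scales, order=1):
    """Independent straightforward DFA-2-norm implementation (oracle)."""
    Y = np.cumsum(x - np.mean(x))
    out = []
    for s in scales:
        n_s = len(Y) // s
        fs = []
        for v in range(n_s):
            seg = Y[v * s : (v + 1) * s]
            t = np.arange(s)
            c = np.polyfit(t, seg, order)
            fs.append(np.mean((seg - np.polyval(c, t)) ** 2))
        out.append(np.sqrt(np.mean(fs)))
    return np.array(out)


class TestScalingFunction:
    def test_q2_equals_classical_dfa(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(2048)
        scales = np.array([16, 32, 64, 128])
        cfg = MfdfaConfig(q_grid=(2.0,), scales=scales)
        surf = scaling_function(x, cfg)
        assert np.allclose(surf.S[0], _plain_dfa(x, scales), rtol=1e-12)

    def test_focus_is_q_independent_at_full_length(self):
        """Eq. at s=L has a single window, so S(q, L) = F(1, L) for all q."""
        rng = np.random.default_rng(4)
        x = rng.standard_normal(1024)
        surf = scaling_function(x, MfdfaConfig())
        Y = profile(x)
        F_full = window_fluctuation(Y, 1, 1024)
        # single-window moment aggregate is F itself for every q
        for q in (-5.0, -1.0, 1.0, 5.0):
            assert np.isclose((F_full**q) ** (1 / q), surf.focus)

    def test_surface_positive_finite(self):
        x = gen_fgn(4096, 0.7, seed=5)
        surf = scaling_function(x, MfdfaConfig())
        assert np.all(np.isfinite(surf.S)) and np.all(surf.S > 0)

    def test_fgn_slope_near_hurst(self):
        x = gen_fgn(2**14, 0.7, seed=6)
        cfg = MfdfaConfig(q_grid=(2.0,))
        H = hurst_curve(scaling_function(x, cfg), cfg).H[0]
        assert 0.65 <= H <= 0.75

    def test_homogeneity_scaling(self):
        """Scaling x by c scales S by |c| and leaves H(q) unchanged."""
        x = gen_fgn(4096, 0.6, seed=7)
        cfg = MfdfaConfig()
        s1 = scaling_function(x, cfg)
        s2 = scaling_function(-3.0 * x, cfg)
        assert np.allclose(s2.S, 3.0 * s1.S, rtol=1e-10)
        h1 = hurst_curve(s1, cfg).H
        h2 = hurst_curve(s2, cfg).H
        assert np.allclose(h1, h2, atol=1e-10)


class TestHurstCurve:
    def test_cascade_matches_analytic(self):
        x, _ = gen_binomial_cascade(14, 0.75)
        cfg = MfdfaConfig()
        curve = hurst_curve(scaling_function(x, cfg), cfg)
        analytic = cascade_hurst(0.75, curve.q_grid)
        assert np.max(np.abs(curve.H - analytic)) < 0.1

    def test_white_noise_flat_at_half(self):
        x = gen_fgn(2**14, 0.5, seed=8)
        cfg = MfdfaConfig()
        curve = hurst_curve(scaling_function(x, cfg), cfg)
        assert np.all(np.abs(curve.H - 0.5) < 0.05)

    def test_focus_regression_matches_scalar_minimization(self):
        """Constrained slopes agree with a brute-force 1-parameter fit.

        The focus-constrained line is log S = log focus + H (log s - log L);
        minimizing the squared error over H alone (scipy scalar optimizer)
        must reproduce the closed-form slope for every q.
        """
        from scipy.optimize import minimize_scalar

        x, _ = gen_binomial_cascade(12, 0.7)
        cfg = MfdfaConfig(fit_mode="focus_regression")
        surf = scaling_function(x, cfg)
        curve = hurst_curve(surf, cfg)
        u = np.log(surf.scales.astype(float)) - np.log(surf.L)
        for i in range(curve.q_grid.size):
            w = np.log(surf.S[i]) - np.log(surf.focus)
            res = minimize_scalar(lambda m: np.sum((w - m * u) ** 2))
            assert np.isclose(curve.H[i], res.x, atol=1e-5)

    def test_nonincreasing_for_cascade(self):
        x, _ = gen_binomial_cascade(14, 0.7)
        cfg = MfdfaConfig()
        curve = hurst_curve(scaling_function(x, cfg), cfg)
        assert np.all(np.diff(curve.H) < 3 * (curve.stderr[:-1] + curve.stderr[1:]))


class TestGroupBand:
    def _curve(self, H):
        q = np.array([-5.0, -1.0, 1.0, 5.0])
        return HurstCurve(q, np.asarray(H, float), np.zeros(4), np.zeros((4, 2)))

    def test_identical_curves_zero_width(self):
        curves = [self._curve([0.7, 0.6, 0.5, 0.4]) for _ in range(5)]
        band = group_hurst_band(curves)
        assert np.allclose(band.ci95[:, 0], band.ci95[:, 1])

    def test_band_contains_mean(self):
        rng = np.random.default_rng(9)
        curves = [self._curve(0.5 + 0.1 * rng.standard_normal(4)) for _ in range(10)]
        band = group_hurst_band(curves)
        assert np.all(band.ci95[:, 0] <= band.H) and np.all(band.H <= band.ci95[:, 1])

    def test_band_covers_generating_hurst(self):
        """50 fGn(H=0.6) curves: the group band covers 0.6 at >= 90% of q."""
        cfg = MfdfaConfig()
        curves = []
        for s in range(50):
            x = gen_fgn(4096, 0.6, seed=s)
            curves.append(hurst_curve(scaling_function(x, cfg), cfg))
        band = group_hurst_band(curves)
        covered = (band.ci95[:, 0] <= 0.6) & (0.6 <= band.ci95[:, 1])
        assert covered.mean() >= 0.9

    def test_mismatched_grids_rejected(self):
        c1 = self._curve([0.5] * 4)
        c2 = HurstCurve(np.array([-3.0, -1.0, 1.0, 3.0]), np.full(4, 0.5),
                        np.zeros(4), np.zeros((4, 2)))
        with pytest.raises(ValueError):
            group_hurst_band([c1, c2])


class TestWasserstein:
    def _curve(self, H):
        q = np.arange(float(len(H)))
        return HurstCurve(q, np.asarray(H, float), np.zeros(len(H)), np.zeros((len(H), 2)))

    def test_identity(self):
        c = self._curve([0.9, 0.7, 0.5])
        assert hq_wasserstein(c, c) == 0.0

    def test_translation(self):
        c1 = self._curve([0.9, 0.7, 0.5, 0.3])
        c2 = self._curve([1.2, 1.0, 0.8, 0.6])
        assert np.isclose(hq_wasserstein(c1, c2), 0.3)

    def test_unit_shift_of_two_point_samples(self):
        c1 = self._curve([0.0, 1.0])
        c2 = self._curve([1.0, 2.0])
        assert np.isclose(hq_wasserstein(c1, c2), 1.0)

    def test_nonfinite_rejected(self):
        c1 = self._curve([0.5, np.nan])
        with pytest.raises(ValueError):
            hq_wasserstein(c1, c1)


class TestMultifractalityReport:
    def test_cascade_flagged_multifractal(self):
        x, _ = gen_binomial_cascade(14, 0.75)
        rep = multifractality_report(x)
        assert rep["delta_h"] > 0.2
        assert rep["multifractal_like"]

    def test_fgn_not_flagged(self):
        x = gen_fgn(2**14, 0.6, seed=10)
        rep = multifractality_report(x)
        assert rep["delta_h"] < 0.1
        assert not rep["multifractal_like"]

    def test_fields_finite(self):
        x = gen_fgn(4096, 0.4, seed=11)
        rep = multifractality_report(x)
        assert np.isfinite(rep["focus_deviation"])
        assert np.isfinite(rep["delta_h"])
        assert np.all(np.isfinite(rep["r2"]))
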