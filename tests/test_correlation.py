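"""Tests of the correlation estimators and the linear-response theory."""

import math

import numpy as np
import pytest

from corrshape.correlation import (
    CountCorrelation,
    coherence,
    count_correlation,
    cross_correlogram,
    current_based_control,
    current_based_spectra,
    default_windows,
    linear_transfer_ratio,
    rho_T_theory,
    shaping_ratio,
    spectral_window_integral,
    susceptibility_fit,
    triangle_weight,
)
from corrshape.simulate import SpikeTrain


def poisson_train(rate_hz, duration, seed):
    rng = np.random.default_rng(seed)
    n = rng.poisson(rate_hz * duration * 1e-3)
    return SpikeTrain(np.sort(rng.uniform(0, duration, n)), duration)


WINDOWS = np.array([5.0, 20.0, 100.0])


class TestCountCorrelation:
    def test_identical_trains_fully_correlated(self):
        tr = poisson_train(20.0, 60_000.0, 1)
        cc = count_correlation(tr, tr, WINDOWS)
        np.testing.assert_allclose(cc.rho, 1.0)

    def test_independent_trains_uncorrelated(self):
        a = poisson_train(20.0, 200_000.0, 2)
        b = poisson_train(20.0, 200_000.0, 3)
        cc = count_correlation(a, b, WINDOWS)
        assert np.all(np.abs(cc.rho) < 3 * cc.se)

    def test_matches_brute_force_on_hand_built_counts(self):
        # 20 two-ms bins with prescribed counts; the estimator must equal the
        # direct covariance/variance computation exactly
        ca = np.array([1, 0, 2, 1, 0, 0, 3, 1, 0, 2, 1, 1, 0, 0, 1, 2, 0, 1, 0, 1])
        cb = np.array([0, 1, 2, 0, 0, 1, 2, 1, 1, 2, 0, 1, 0, 1, 1, 1, 0, 0, 0, 2])
        T = 2.0
        ta = np.concatenate([i * T + np.linspace(0.3, 1.7, c) for i, c in enumerate(ca) if c])
        tb = np.concatenate([i * T + np.linspace(0.2, 1.8, c) for i, c in enumerate(cb) if c])
        a = SpikeTrain(np.sort(ta), 40.0)
        b = SpikeTrain(np.sort(tb), 40.0)
        cc = count_correlation(a, b, np.array([T]))
        da, db = ca - ca.mean(), cb - cb.mean()
        brute = np.sum(da * db) / math.sqrt(np.sum(da**2) * np.sum(db**2))
        assert cc.rho[0] == pytest.approx(brute, abs=1e-12)

    def test_relabeling_invariance(self, corr_sims):
        res = corr_sims["low"]
        ab = count_correlation(res.trains[0], res.trains[1], WINDOWS)
        ba = count_correlation(res.trains[1], res.trains[0], WINDOWS)
        np.testing.assert_allclose(ab.rho, ba.rho)

    def test_zero_variance_flagged_not_raised(self):
        a = poisson_train(20.0, 10_000.0, 4)
        silent = SpikeTrain(np.array([]), 10_000.0)
        cc = count_correlation(a, silent, WINDOWS)
        assert np.all(np.isnan(cc.rho))


class TestCrossCorrelogram:
    def test_independent_trains_flat(self):
        a = poisson_train(30.0, 100_000.0, 5)
        b = poisson_train(30.0, 100_000.0, 6)
        lags, C = cross_correlogram(a, b, max_lag=20.0, bin=2.0)
        # counting noise of the pair histogram: sqrt(rA rB T bin) pairs/bin
        se = math.sqrt(0.03 * 0.03 * 100_000.0 * 2.0) / (100_000.0 * 2.0) * 1e6
        assert np.all(np.abs(C) < 4 * se)

    def test_identical_trains_peak_at_zero_lag(self):
        a = poisson_train(30.0, 50_000.0, 7)
        lags, C = cross_correlogram(a, a, max_lag=10.0, bin=1.0)
        assert C[np.argmin(np.abs(lags))] == np.max(C)
        assert C[np.argmin(np.abs(lags))] > 10 * np.abs(np.delete(C, np.argmin(np.abs(lags)))).max()

    def test_swap_symmetry(self, corr_sims):
        res = corr_sims["low"]
        lags, Cab = cross_correlogram(res.trains[0], res.trains[1], 20.0, 2.0)
        _, Cba = cross_correlogram(res.trains[1], res.trains[0], 20.0, 2.0)
        # spike times are multiples of dt, so a lag can sit exactly on a bin
        # edge and flip sides under the swap: allow a few boundary counts
        one_count = 1e6 / (res.trains[0].duration * 2.0)
        np.testing.assert_allclose(Cab, Cba[::-1], atol=3 * one_count)

    def test_zero_lag_peak_larger_in_high_state(self, corr_sims):
        peaks = {}
        for label, res in corr_sims.items():
            lags, C = cross_correlogram(res.trains[0], res.trains[1], 20.0, 1.0)
            peaks[label] = C[np.argmin(np.abs(lags))]
        assert peaks["high"] > peaks["low"]


class TestCoherence:
    def test_identical_trains_have_unit_coherence(self):
        a = poisson_train(40.0, 100_000.0, 8)
        f, coh = coherence(a, a)
        band = (f > 1) & (f < 400)
        assert np.all(coh[band] > 0.99)

    def test_independent_trains_near_zero(self):
        a = poisson_train(40.0, 200_000.0, 9)
        b = poisson_train(40.0, 200_000.0, 10)
        f, coh = coherence(a, b)
        band = (f > 1) & (f < 400)
        # Welch magnitude coherence has a positive small-sample floor ~1/sqrt(n_seg)
        assert np.mean(coh[band]) < 0.15

    def test_symmetric_in_inputs(self, corr_sims):
        res = corr_sims["low"]
        _, ab = coherence(res.trains[0], res.trains[1])
        _, ba = coherence(res.trains[1], res.trains[0])
        np.testing.assert_allclose(ab, ba, rtol=1e-9)


class TestTriangleWeight:
    def test_zero_frequency_value(self):
        for T in (1.0, 37.0, 500.0):
            assert triangle_weight(T, np.array([0.0]))[0] == pytest.approx(T * T)

    def test_zeros_at_harmonics_of_inverse_window(self):
        T = 25.0
        f = np.array([1, 2, 3, 7]) / T * 1e3  # Hz
        np.testing.assert_allclose(triangle_weight(T, f), 0.0, atol=1e-9 * T * T)

    def test_matches_fft_of_sampled_triangle(self):
        # independent oracle: FFT of the finely sampled triangle kernel,
        # compared below the kernel's first zero where discretization error
        # (O((pi f dt)^2)) sits under the tolerance
        T = 20.0
        dt = 0.001
        tau = np.arange(-T, T, dt)
        tri = T - np.abs(tau)
        n_pad = 1 << 22
        F = np.fft.rfft(tri, n=n_pad) * dt
        freqs_khz = np.fft.rfftfreq(n_pad, d=dt)
        sel = (freqs_khz > 0) & (freqs_khz < 0.045)
        K_fft = np.abs(F[sel])
        K_closed = triangle_weight(T, freqs_khz[sel] * 1e3)
        np.testing.assert_allclose(K_fft, K_closed, rtol=1e-6)

    def test_small_window_weighting_flattens(self):
        f = np.linspace(0.0, 900.0, 10)
        k_small = triangle_weight(0.1, f) / 0.1**2
        assert k_small.min() > 0.95  # ~flat across the band


class TestRhoTheory:
    def test_zero_input_correlation_gives_zero(self, spectra, eff_pair):
        spec = spectra[0]
        cc = rho_T_theory(spec, eff_pair[0].sigma, 0.0, WINDOWS)
        np.testing.assert_allclose(cc.rho, 0.0)

    def test_linear_in_input_correlation(self, spectra, eff_pair):
        spec = spectra[0]
        r1 = rho_T_theory(spec, eff_pair[0].sigma, 0.05, WINDOWS).rho
        r2 = rho_T_theory(spec, eff_pair[0].sigma, 0.10, WINDOWS).rho
        np.testing.assert_allclose(r2, 2 * r1, rtol=1e-9)

    def test_long_window_limit_is_zero_frequency_ratio(self, spectra, eff_pair):
        for spec, eff in zip(spectra, eff_pair):
            rho_inf = 0.1 * eff.sigma**2 * abs(spec.A[0] * 1e-3) ** 2 / (spec.S[0] * 1e-3)
            rho_T = rho_T_theory(spec, eff.sigma, 0.1, np.array([10_000.0])).rho[0]
            assert rho_T == pytest.approx(rho_inf, rel=0.01)

    def test_matches_paired_simulation_for_weak_correlation(self, spectra, eff_pair, corr_sims):
        T_grid = np.array([3.0, 10.0, 50.0, 200.0])
        for (label, res), spec, eff in zip(corr_sims.items(), spectra, eff_pair):
            sim = count_correlation(res.trains[0], res.trains[1], T_grid)
            th = rho_T_theory(spec, eff.sigma, 0.1, T_grid)
            for i in range(len(T_grid)):
                assert abs(sim.rho[i] - th.rho[i]) < 3 * sim.se[i] + 0.005

    def test_too_small_window_raises_grid_error(self, spectra, eff_pair):
        with pytest.raises(ValueError):
            rho_T_theory(spectra[0], eff_pair[0].sigma, 0.1, np.array([0.1]))


class TestShapingRatio:
    def test_identical_inputs_give_unit_ratio(self, spectra, eff_pair):
        cc = rho_T_theory(spectra[0], eff_pair[0].sigma, 0.1, WINDOWS)
        sc = shaping_ratio(cc, cc)
        np.testing.assert_allclose(sc.ratio, 1.0)
        assert len(sc.crossings) == 0

    def test_canonical_states_shape_with_single_crossing(self, spectra, eff_pair):
        W = default_windows()
        low = rho_T_theory(spectra[0], eff_pair[0].sigma, 0.1, W)
        high = rho_T_theory(spectra[1], eff_pair[1].sigma, 0.1, W)
        sc = shaping_ratio(low, high)
        assert np.all(np.diff(sc.ratio) < 0)  # decreasing in T
        assert len(sc.crossings) == 1
        assert sc.ratio[0] > 1.0 > sc.ratio[-1]

    def test_masks_windows_with_undetectable_baseline(self):
        w = np.array([1.0, 2.0])
        low = CountCorrelation(w, np.array([0.001, 0.05]), np.array([0.01, 0.001]))
        high = CountCorrelation(w, np.array([0.01, 0.05]), np.array([0.001, 0.001]))
        sc = shaping_ratio(low, high)
        assert math.isnan(sc.ratio[0]) and math.isfinite(sc.ratio[1])


class TestSusceptibility:
    def test_theory_slope_recovers_rho_over_c(self, spectra, eff_pair):
        spec, eff = spectra[0], eff_pair[0]
        results = {c: rho_T_theory(spec, eff.sigma, c, WINDOWS) for c in (0.05, 0.1, 0.2)}
        model = susceptibility_fit(results)
        expected = rho_T_theory(spec, eff.sigma, 1.0, WINDOWS).rho
        np.testing.assert_allclose(model.slope, expected, rtol=1e-9)
        np.testing.assert_allclose(model.residual_rms, 0.0, atol=1e-12)

    def test_simulated_correlations_fit_linearly(self, states):
        from corrshape.simulate import simulate_pair_diffusion

        low, _ = states
        T_grid = np.array([10.0, 100.0])
        results = {}
        for c in (0.1, 0.2):
            res = simulate_pair_diffusion(low, c=c, duration=120_000.0, seed=int(100 * c))
            results[c] = count_correlation(res.trains[0], res.trains[1], T_grid)
        model = susceptibility_fit(results)
        # residuals from the origin-constrained fit stay within Monte-Carlo error
        for c in (0.1, 0.2):
            resid = results[c].rho - c * model.slope
            assert np.all(np.abs(resid) < 3 * results[c].se + 0.005)


class TestControls:
    def test_linear_transfer_cannot_shape(self):
        W = default_windows()
        np.testing.assert_allclose(linear_transfer_ratio(W), 1.0, atol=1e-12)

    def test_current_based_control_shapes_less_than_conductance(self, states, spectra, eff_pair):
        # the fixed-tau control never favors one timescale over the other the
        # way the conductance model does: its ratio curve spans far less and
        # never crosses 1, while the conductance ratio crosses once
        W = default_windows()
        low = rho_T_theory(spectra[0], eff_pair[0].sigma, 0.1, W)
        high = rho_T_theory(spectra[1], eff_pair[1].sigma, 0.1, W)
        cond = shaping_ratio(low, high)
        ctrl = current_based_control(states, c_in=0.1, windows=W)
        assert ctrl.ratio.max() - ctrl.ratio.min() < 0.5 * (cond.ratio.max() - cond.ratio.min())
        assert len(ctrl.crossings) == 0
        assert len(cond.crossings) == 1

    def test_high_frequency_transfer_preference_needs_conductance(self, states, spectra):
        # the noise-weighted transfer ratio sigma_h|A_h| / sigma_l|A_l| rises
        # with frequency only when the membrane speeds up (conductance model)
        sl, sh = current_based_spectra(states)
        f = sl.freqs
        i1 = np.argmin(np.abs(f - 1.0))
        i2 = np.argmin(np.abs(f - 100.0))
        s_ratio_ctrl = (sh.sigma * np.abs(sh.A)) / (sl.sigma * np.abs(sl.A))
        s_ratio_cond = (spectra[1].sigma * np.abs(spectra[1].A)) / (
            spectra[0].sigma * np.abs(spectra[0].A)
        )
        assert s_ratio_cond[i2] > 1.2 * s_ratio_cond[i1]
        assert s_ratio_ctrl[i2] <= s_ratio_ctrl[i1]

    def test_count_variance_denominator_state_dependence(self, spectra):
        # windowed variance integral: state-equal at small T, larger for the
        # high state at large T (its low-frequency power is higher)
        sl, sh = spectra
        for T, should_differ in ((1.0, False), (500.0, True)):
            vl = spectral_window_integral(sl.freqs, sl.S * 1e-3, T)
            vh = spectral_window_integral(sh.freqs, sh.S * 1e-3, T)
            if should_differ:
                assert vh > 1.3 * vl
            else:
                assert vh == pytest.approx(vl, rel=0.1)


class TestShotNoiseConsistency:
    def test_shot_noise_shaping_ratio_tracks_diffusion_limit(self, states, spectra, eff_pair):
        # the diffusion approximation must reproduce the shot-noise model's
        # correlation shaping at the reference states
        from corrshape.simulate import simulate_pair_shotnoise

        T_grid = np.array([3.0, 50.0])
        rho = {}
        for st in states:
            res = simulate_pair_shotnoise(st, c=0.5, duration=400_000.0, seed=31)
            rho[st.label] = count_correlation(res.trains[0], res.trains[1], T_grid)
        shot_ratio = rho["high"].rho / rho["low"].rho
        low = rho_T_theory(spectra[0], eff_pair[0].sigma, 0.5, T_grid)
        high = rho_T_theory(spectra[1], eff_pair[1].sigma, 0.5, T_grid)
        diff_ratio = high.rho / low.rho
        np.testing.assert_allclose(shot_ratio, diff_ratio, rtol=0.15)
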