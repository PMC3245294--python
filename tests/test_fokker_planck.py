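"""Tests of the threshold-integration solver against independent oracles.

The oracles are deliberately different machinery: the classical
mean-first-passage quadrature (Siegert-type, via erfcx), the deterministic
LIF closed form, empirical ISI statistics from stochastic simulation, and a
perturbed simulation with an injected sinusoid for the transfer function.
"""

import cmath
import math

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.special import erfcx

from corrshape.model import EffectiveDiffusion, NeuronParams
from corrshape import fokker_planck as fpk
from conftest import simulate_modulated

NEURON = NeuronParams()
SUBTHRESHOLD = EffectiveDiffusion(g_tot=18.4, tau_eff=10.85, V_inf=-52.9, sigma=0.172)


def siegert_mean_cv(eff, neuron):
    """Stable quadrature for the OU first-passage mean and CV."""
    tau = eff.tau_eff
    sv = (eff.sigma / neuron.C) * math.sqrt(tau / 2.0)
    xr = (neuron.V_r - eff.V_inf) / (sv * math.sqrt(2))
    xt = (neuron.V_th - eff.V_inf) / (sv * math.sqrt(2))
    mean = tau * math.sqrt(math.pi) * quad(lambda u: erfcx(-u), xr, xt, limit=200)[0]
    inner = lambda x: quad(lambda y: erfcx(-y) ** 2 * math.exp(x * x - y * y), -30.0 + 0 * x, x, limit=200)[0]
    var = tau**2 * 2 * math.pi * quad(inner, xr, xt, limit=200)[0]
    return mean, math.sqrt(var) / mean


class TestSteadyStateRate:
    def test_deterministic_suprathreshold_closed_form(self):
        eff = EffectiveDiffusion(g_tot=18.4, tau_eff=10.85, V_inf=-45.0, sigma=1e-3 * 10 * NEURON.C)
        exact = 1e3 / (10.85 * math.log((-45.0 + 60.0) / (-45.0 + 50.0)))
        assert fpk.steady_state_rate(eff, NEURON, n=8192) == pytest.approx(exact, rel=0.01)

    def test_zero_noise_subthreshold_is_silent(self):
        eff = EffectiveDiffusion(g_tot=18.4, tau_eff=10.85, V_inf=-55.0, sigma=0.0)
        assert fpk.steady_state_rate(eff, NEURON) == 0.0

    @pytest.mark.parametrize("v_inf,sigma", [(-52.9, 0.172), (-55.6, 0.37), (-48.0, 0.10)])
    def test_rate_matches_siegert_quadrature(self, v_inf, sigma):
        eff = EffectiveDiffusion(g_tot=20.0, tau_eff=10.0, V_inf=v_inf, sigma=sigma)
        mean, _ = siegert_mean_cv(eff, NEURON)
        assert fpk.steady_state_rate(eff, NEURON) == pytest.approx(1e3 / mean, rel=0.005)

    def test_grid_refinement_stability(self):
        r1 = fpk.steady_state_rate(SUBTHRESHOLD, NEURON, n=4096)
        r2 = fpk.steady_state_rate(SUBTHRESHOLD, NEURON, n=8192)
        assert r2 == pytest.approx(r1, rel=1e-3)

    def test_rate_matches_long_simulation(self, states, eff_pair, long_sims):
        # Euler-Maruyama under-counts crossings by O(sqrt(dt)); allow that
        # documented bias (~3%) on top of the Monte-Carlo band
        for st, eff in zip(states, eff_pair):
            r_fp = fpk.steady_state_rate(eff, st.neuron)
            tr = long_sims[st.label].trains[0]
            mc_se = math.sqrt(len(tr.times)) / tr.duration * 1e3
            assert abs(tr.rate - r_fp) < 3 * mc_se + 0.035 * r_fp


class TestIsiMoments:
    def test_moments_match_siegert_quadrature(self):
        mean_fp, cv_fp = fpk.isi_moments(SUBTHRESHOLD, NEURON)
        mean_s, cv_s = siegert_mean_cv(SUBTHRESHOLD, NEURON)
        assert mean_fp == pytest.approx(mean_s, rel=0.005)
        assert cv_fp == pytest.approx(cv_s, rel=0.005)

    def test_mean_isi_consistent_with_rate(self, eff_pair, states):
        for st, eff in zip(states, eff_pair):
            mean, _ = fpk.isi_moments(eff, st.neuron)
            assert 1e3 / mean == pytest.approx(fpk.steady_state_rate(eff, st.neuron), rel=1e-3)


class TestFptTransform:
    def test_zero_frequency_normalization(self):
        fh = fpk.fpt_transform(SUBTHRESHOLD, NEURON, np.array([0.0]))
        assert fh[0] == pytest.approx(1.0)

    def test_magnitude_bounded_and_vanishing_at_high_frequency(self):
        freqs = np.array([1.0, 5.0, 20.0, 100.0, 1000.0, 3000.0])
        fh = fpk.fpt_transform(SUBTHRESHOLD, NEURON, freqs)
        assert np.all(np.abs(fh) <= 1.0 + 1e-9)
        assert abs(fh[-1]) < 1e-6

    def test_matches_empirical_isi_characteristic_function(self, states, eff_pair, long_sims):
        low, _ = states
        effl, _ = eff_pair
        isi = np.concatenate([np.diff(tr.times) for tr in long_sims["low"].trains])
        for f in (2.0, 5.0, 10.0):
            fh = fpk.fpt_transform(effl, low.neuron, np.array([f]))[0]
            z = np.exp(-2j * math.pi * f * 1e-3 * isi)
            emp = z.mean()
            se = np.std(z.real) / math.sqrt(len(z)) + 1j * np.std(z.imag) / math.sqrt(len(z))
            assert abs(emp.real - fh.real) < 3 * se.real + 5e-3
            assert abs(emp.imag - fh.imag) < 3 * se.imag + 5e-3


class TestPowerSpectrum:
    def test_high_frequency_limit_is_rate(self, states, eff_pair):
        for st, eff in zip(states, eff_pair):
            r0 = fpk.steady_state_rate(eff, st.neuron)
            S = fpk.power_spectrum(eff, st.neuron, np.array([1900.0, 2000.0]))
            assert S[-1] == pytest.approx(r0, rel=0.02)

    def test_zero_frequency_limit_is_rate_times_cv_squared(self, states, eff_pair, long_sims):
        # renewal identity S(0) = r0 CV^2, CV taken from simulated ISIs
        for st, eff in zip(states, eff_pair):
            S0 = fpk.power_spectrum(eff, st.neuron, np.array([0.0]))[0]
            isi = np.concatenate([np.diff(tr.times) for tr in long_sims[st.label].trains])
            cv_sim = isi.std(ddof=1) / isi.mean()
            r0 = fpk.steady_state_rate(eff, st.neuron)
            assert S0 == pytest.approx(r0 * cv_sim**2, rel=0.05)

    def test_low_frequency_power_larger_in_high_state(self, states, eff_pair):
        vals = {}
        for st, eff in zip(states, eff_pair):
            vals[st.label] = fpk.power_spectrum(eff, st.neuron, np.array([0.5, 1.0, 2.0]))
        assert np.all(vals["high"] > vals["low"])

    def test_nonnegative_everywhere(self, states, eff_pair, spectra):
        for spec in spectra:
            assert np.all(spec.S >= 0.0)


class TestTransferFunction:
    def test_static_gain_continuity_at_low_frequency(self, states, eff_pair):
        # the f -> 0 modulation solve must join the finite-difference gain
        for st, eff in zip(states, eff_pair):
            A = fpk.transfer_function(eff, st.neuron, np.array([0.0, 0.01]))
            assert abs(A[1]) == pytest.approx(abs(A[0]), rel=0.01)
            assert np.isfinite(A).all()

    def test_magnitude_decays_with_frequency(self, spectra):
        for spec in spectra:
            mag = np.abs(spec.A[1:])  # skip the f = 0 static-gain column
            freqs = spec.freqs[1:]
            coarse = [mag[(freqs >= a) & (freqs < b)].mean() for a, b in
                      ((0.25, 5), (5, 50), (50, 500), (500, 2000))]
            assert all(x > y for x, y in zip(coarse, coarse[1:]))

    def test_matches_perturbed_simulation_at_5hz(self, states, eff_pair):
        low, _ = states
        eff, _ = eff_pair
        f = 5.0
        eps = 0.03  # nA, ~2% of the rheobase-scale current
        blocks = []
        for seed in range(8):
            tspk = simulate_modulated(eff, low.neuron, eps, f, duration=40_000.0, seed=seed)
            z = np.exp(-2j * math.pi * f * 1e-3 * tspk)
            blocks.append(2.0 / 40.0 * z.sum())  # Hz amplitude estimate
        blocks = np.asarray(blocks)
        est = blocks.mean() / eps
        se = blocks.std(ddof=1) / math.sqrt(len(blocks)) / eps
        A = fpk.transfer_function(eff, low.neuron, np.array([f]))[0]
        assert abs(abs(est) - abs(A)) < 3 * se

    def test_gain_ratio_between_states_rises_with_frequency(self, spectra):
        # conductance model: high/low transfer ratio grows toward high f
        sl, sh = spectra
        ratio = np.abs(sh.A) / np.abs(sl.A)
        i1 = np.argmin(np.abs(sl.freqs - 1.0))
        i2 = np.argmin(np.abs(sl.freqs - 100.0))
        assert ratio[i2] > 1.15 * ratio[i1]


class TestGainCurve:
    def test_monotone_and_self_consistent(self, states):
        from corrshape.model import effective_params
        from dataclasses import replace

        low, _ = states
        grid = np.linspace(1.0, 2.5, 6)
        rates = fpk.gain_curve(low.neuron, low.drive, grid)
        assert np.all(np.diff(rates) > 0)
        eff = effective_params(low.neuron, replace(low.drive, nu_E=grid[2]))
        assert rates[2] == pytest.approx(fpk.steady_state_rate(eff, low.neuron))

    def test_zero_excitation_strong_inhibition_is_silent(self, states):
        from dataclasses import replace

        low, _ = states
        rates = fpk.gain_curve(low.neuron, replace(low.drive, nu_I=20.0), np.array([0.0]))
        assert rates[0] < 0.01

    def test_gain_reduced_in_high_state_at_operating_point(self, states):
        # slope of rate vs nu_E at the 15 Hz balanced point
        gains = {}
        for st in states:
            nu0 = st.drive.nu_E
            d = 0.02 * nu0
            r = fpk.gain_curve(st.neuron, st.drive, np.array([nu0 - d, nu0 + d]))
            gains[st.label] = (r[1] - r[0]) / (2 * d)
        assert gains["high"] < gains["low"]
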