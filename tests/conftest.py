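"""Shared fixtures: canonical states, spectral theory, and long simulations.

Long stochastic simulations are session-scoped so the acceptance-level
checks and the unit tests share them instead of re-integrating.
"""

from __future__ import annotations

import math

import numba
import numpy as np
import pytest

from corrshape.model import canonical_states, effective_params
from corrshape import fokker_planck as fpk
from corrshape.simulate import simulate_pair_diffusion


@pytest.fixture(scope="session")
def states():
    """Canonical low/high balanced states (inhibition calibrated to 15 Hz)."""
    return canonical_states()


@pytest.fixture(scope="session")
def eff_pair(states):
    low, high = states
    return (
        effective_params(low.neuron, low.drive),
        effective_params(high.neuron, high.drive),
    )


@pytest.fixture(scope="session")
def spectra(states, eff_pair):
    low, high = states
    effl, effh = eff_pair
    return (
        fpk.spectral_response(effl, low.neuron),
        fpk.spectral_response(effh, high.neuron),
    )


@pytest.fixture(scope="session")
def long_sims(states):
    """200 s independent-pair simulations of both states (rate/CV statistics)."""
    low, high = states
    return {
        "low": simulate_pair_diffusion(low, c=0.0, duration=200_000.0, seed=101),
        "high": simulate_pair_diffusion(high, c=0.0, duration=200_000.0, seed=102),
    }


@pytest.fixture(scope="session")
def corr_sims(states):
    """300 s correlated-pair simulations at c = 0.1 for both states."""
    low, high = states
    return {
        "low": simulate_pair_diffusion(low, c=0.1, duration=300_000.0, seed=201),
        "high": simulate_pair_diffusion(high, c=0.1, duration=300_000.0, seed=202),
    }


@numba.njit(cache=True)
def _modulated_lif_kernel(tau, V_inf, beta_dt, amp_mV_dt, omega, V_th, V_r, V0,
                          n_steps, dt, seed, max_spikes):
    np.random.seed(seed)
    V = V0
    out = np.empty(max_spikes)
    n = 0
    for k in range(n_steps):
        t = k * dt
        V += dt * (-(V - V_inf) / tau) + amp_mV_dt * math.cos(omega * t) + \
            beta_dt * np.random.standard_normal()
        if V >= V_th:
            if n < max_spikes:
                out[n] = (k + 1) * dt
                n += 1
            V = V_r
    return out[:n]


def simulate_modulated(eff, neuron, eps_nA, f_hz, duration, dt=0.005, seed=0):
    """Single LIF with an injected sinusoidal current eps*cos(2 pi f t)."""
    beta = eff.sigma / neuron.C
    omega = 2 * math.pi * f_hz * 1e-3
    amp = eps_nA / neuron.C * dt  # (nA/nF)*ms = mV
    n_steps = int(round(duration / dt))
    return _modulated_lif_kernel(
        eff.tau_eff, eff.V_inf, beta * math.sqrt(dt), amp, omega,
        neuron.V_th, neuron.V_r, neuron.E_L, n_steps, dt, seed,
        int(duration * 0.3) + 64,
    )
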