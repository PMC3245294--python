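"""Threshold-integration solver for the diffusion-limit LIF neuron.

Given the effective Ornstein-Uhlenbeck voltage dynamics

    dV/dt = -(V - V_inf)/tau_eff + (sigma/C) xi(t),

with absorbing threshold ``V_th`` and reset ``V_r``, this module computes

* the steady-state firing rate (stationary Fokker-Planck equation with
  reinjection flux at the reset),
* the Fourier transform of the first-passage-time (ISI) density,
* the spike-train power spectrum through the renewal relation
  ``S(f) = r0 (1 - |fhat|^2) / |1 - fhat|^2``,
* the linear-response transfer function ``A(f)`` for a small injected
  sinusoidal current.

All solvers integrate the probability flux and density downward from
threshold on a uniform voltage grid, the standard "threshold integration"
scheme for this solver family.  Each integration step treats the drift as
constant over the step and uses the exact exponential update, which keeps
the scheme stable for strongly subthreshold (stiff) parameter ranges.

Frequencies at the public surface are in Hz, rates in Hz, currents in nA;
internally the solver works in ms/kHz units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .model import EffectiveDiffusion, NeuronParams, SynapticDrive, effective_params

__all__ = [
    "SpectralResponse",
    "steady_state_rate",
    "isi_moments",
    "fpt_transform",
    "power_spectrum",
    "transfer_function",
    "spectral_response",
    "gain_curve",
    "default_freq_grid",
    "FokkerPlanckError",
]

DEFAULT_N_GRID = 4096


class FokkerPlanckError(RuntimeError):
    """Raised when a threshold-integration solve fails to produce finite values."""


@dataclass(frozen=True)
class SpectralResponse:
    """Frequency-domain characterization of one neuron in one input state.

    freqs : frequency grid (Hz); A : complex transfer function (Hz/nA);
    S : spike-train power spectrum (Hz); r0 : steady-state rate (Hz);
    sigma : the input-current noise intensity (nA*sqrt(ms)) the state was
    evaluated at, carried along for the correlation theory.
    """

    freqs: np.ndarray
    A: np.ndarray
    S: np.ndarray
    r0: float
    sigma: float


# ---------------------------------------------------------------------------
# grid and elementary stepping
# ---------------------------------------------------------------------------


def _grid(eff: EffectiveDiffusion, neuron: NeuronParams, n: int):
    """Uniform voltage grid from a lower reflecting bound up to V_th.

    The reset potential is snapped onto a grid node.  The lower bound sits
    10 stationary standard deviations below min(V_r, V_inf) (truncation error
    ~exp(-50)), bounded below by ``E_I - 10`` mV: far-subthreshold voltages
    carry no probability mass and deep bounds only cost conditioning.
    """
    beta = eff.sigma / neuron.C  # mV / sqrt(ms)
    sigma_v = beta * math.sqrt(eff.tau_eff / 2.0)
    depth = max(10.0 * sigma_v, 0.05 * (neuron.V_th - neuron.V_r))
    V_lb = max(neuron.E_I - 10.0, min(neuron.V_r, eff.V_inf) - depth)
    # snap V_r onto the grid
    dv0 = (neuron.V_th - V_lb) / n
    n_up = max(1, round((neuron.V_th - neuron.V_r) / dv0))
    dv = (neuron.V_th - neuron.V_r) / n_up
    n_down = max(1, math.ceil((neuron.V_r - V_lb) / dv))
    V = neuron.V_th - dv * np.arange(n_up + n_down + 1)  # descending, V[0]=V_th
    i_reset = n_up  # V[i_reset] == V_r
    return V, dv, i_reset


def _drift_mid(V: np.ndarray, eff: EffectiveDiffusion) -> np.ndarray:
    """Drift F(V) = -(V - V_inf)/tau_eff evaluated at interval midpoints."""
    Vm = 0.5 * (V[:-1] + V[1:])
    return -(Vm - eff.V_inf) / eff.tau_eff


def _exp_factors(a: np.ndarray, dv: float):
    """E = exp(-a dv) and G = (E - 1)/a with the a -> 0 limit handled."""
    x = a * dv
    E = np.exp(-x)
    small = np.abs(x) < 1e-12
    with np.errstate(divide="ignore", invalid="ignore"):
        G = np.where(small, -dv, (E - 1.0) / np.where(small, 1.0, a))
    return E, G


# ---------------------------------------------------------------------------
# steady state
# ---------------------------------------------------------------------------


def _steady_density(eff: EffectiveDiffusion, neuron: NeuronParams, n: int):
    """Stationary density (normalized) and rate (kHz) by threshold integration."""
    D = 0.5 * (eff.sigma / neuron.C) ** 2  # mV^2/ms
    if D <= 0.0:
        raise FokkerPlanckError("steady-state density requires sigma > 0")
    V, dv, i_reset = _grid(eff, neuron, n)
    F = _drift_mid(V, eff)
    E, G = _exp_factors(F / D, dv)
    p = np.empty_like(V)
    p[0] = 0.0
    with np.errstate(over="ignore"):
        for k in range(len(V) - 1):
            j = 1.0 if k < i_reset else 0.0  # unit flux above the reset, none below
            p[k + 1] = p[k] * E[k] + (-j / D) * G[k]
        mass = np.trapezoid(p[::-1], V[::-1])
    if np.isnan(mass) or mass <= 0:
        raise FokkerPlanckError("steady-state solve produced non-finite density")
    if np.isinf(mass):
        # mean first-passage time beyond float range: silent to all precision
        return V, np.zeros_like(p), 0.0
    r0 = 1.0 / mass  # kHz
    return V, p * r0, r0


def steady_state_rate(
    eff: EffectiveDiffusion, neuron: NeuronParams, n: int = DEFAULT_N_GRID
) -> float:
    """Steady-state firing rate (Hz) of the diffusion-limit LIF.

    For ``sigma = 0`` the deterministic closed form is used: zero below
    threshold, ``1/(tau_eff ln[(V_inf - V_r)/(V_inf - V_th)])`` above.
    """
    if eff.sigma == 0.0:
        if eff.V_inf <= neuron.V_th:
            return 0.0
        return 1e3 / (
            eff.tau_eff * math.log((eff.V_inf - neuron.V_r) / (eff.V_inf - neuron.V_th))
        )
    _, _, r0 = _steady_density(eff, neuron, n)
    return r0 * 1e3


# ---------------------------------------------------------------------------
# first-passage-time transform and ISI moments
# ---------------------------------------------------------------------------


def _fpt_branch(V, dv, D, F, omegas, start: int):
    """Integrate the homogeneous frequency-domain system downward from V[start].

    Returns the flux j(V_lb) for each angular frequency (rad/ms), for the
    branch with p(V[start]) = 0, j(V[start]) = 1.
    """
    E, G = _exp_factors(F / D, dv)
    p = np.zeros(len(omegas), dtype=complex)
    j = np.ones(len(omegas), dtype=complex)
    iw = 1j * omegas
    for k in range(start, len(V) - 1):
        p_new = p * E[k] + (-j / D) * G[k]
        j = j + iw * dv * 0.5 * (p + p_new)
        p = p_new
    return j


def fpt_transform(
    eff: EffectiveDiffusion,
    neuron: NeuronParams,
    freqs: np.ndarray,
    n: int = DEFAULT_N_GRID,
) -> np.ndarray:
    """Fourier transform of the first-passage-time (ISI) density.

    The absorbing-boundary problem with the source at the reset is solved by
    two downward integrations, one started at threshold and one at the reset;
    the ratio of their fluxes at the lower bound gives ``fhat``.  ``fhat(0) = 1``
    exactly (normalization of the ISI density) and ``|fhat| <= 1``.
    """
    freqs = np.asarray(freqs, dtype=float)
    D = 0.5 * (eff.sigma / neuron.C) ** 2
    if D <= 0.0:
        raise FokkerPlanckError("fpt_transform requires sigma > 0")
    V, dv, i_reset = _grid(eff, neuron, n)
    F = _drift_mid(V, eff)
    omegas = 2.0 * math.pi * freqs * 1e-3  # rad/ms
    nonzero = omegas != 0.0
    out = np.ones(len(freqs), dtype=complex)
    if np.any(nonzero):
        w = omegas[nonzero]
        j_th = _fpt_branch(V, dv, D, F, w, start=0)
        j_re = _fpt_branch(V, dv, D, F, w, start=i_reset)
        fh = j_re / j_th
        if not np.all(np.isfinite(fh)):
            bad = freqs[nonzero][~np.isfinite(fh)][0]
            raise FokkerPlanckError(f"first-passage solve diverged at f = {bad:g} Hz")
        out[nonzero] = fh
    return out


def _moment_branch(V, dv, D, F, start: int):
    """Small-frequency expansion coefficients J1, J2 of a flux branch."""
    E, G = _exp_factors(F / D, dv)
    P0 = 0.0
    J1 = 0.0
    P1 = 0.0
    J2 = 0.0
    for k in range(start, len(V) - 1):
        P0n = P0 * E[k] + (-1.0 / D) * G[k]
        J1 = J1 + dv * 0.5 * (P0 + P0n)
        P1n = P1 * E[k] + (-J1 / D) * G[k]  # J1 at the lower node; O(dv^2) locally
        J2 = J2 + dv * 0.5 * (P1 + P1n)
        P0, P1 = P0n, P1n
    return J1, J2


def isi_moments(
    eff: EffectiveDiffusion, neuron: NeuronParams, n: int = DEFAULT_N_GRID
) -> tuple[float, float]:
    """Mean ISI (ms) and coefficient of variation from the FPT expansion.

    Expanding the two flux branches of :func:`fpt_transform` to second order
    in frequency yields the first two moments of the first-passage time:
    ``<t> = H1 - S1`` and ``<t^2> = 2 (S2 - H2 + H1 (H1 - S1))``.
    """
    D = 0.5 * (eff.sigma / neuron.C) ** 2
    if D <= 0.0:
        raise FokkerPlanckError("isi_moments requires sigma > 0")
    V, dv, i_reset = _grid(eff, neuron, n)
    F = _drift_mid(V, eff)
    H1, H2 = _moment_branch(V, dv, D, F, start=0)
    S1, S2 = _moment_branch(V, dv, D, F, start=i_reset)
    mean = H1 - S1
    second = 2.0 * (S2 - H2 + H1 * (H1 - S1))
    var = second - mean**2
    if mean <= 0 or var < 0:
        raise FokkerPlanckError("ISI moment expansion produced unphysical values")
    return mean, math.sqrt(var) / mean


# ---------------------------------------------------------------------------
# power spectrum and transfer function
# ---------------------------------------------------------------------------


def power_spectrum(
    eff: EffectiveDiffusion,
    neuron: NeuronParams,
    freqs: np.ndarray,
    n: int = DEFAULT_N_GRID,
) -> np.ndarray:
    """Spike-train power spectrum (Hz) via the renewal relation.

    ``S(f) = r0 (1 - |fhat|^2)/|1 - fhat|^2``; the ``f = 0`` entry is the
    analytic renewal limit ``r0 CV^2`` rather than the singular quotient.
    """
    freqs = np.asarray(freqs, dtype=float)
    r0 = steady_state_rate(eff, neuron, n)  # Hz
    fh = fpt_transform(eff, neuron, freqs, n)
    S = np.empty(len(freqs))
    zero = freqs == 0.0
    if np.any(zero):
        _, cv = isi_moments(eff, neuron, n)
        S[zero] = r0 * cv**2
    nz = ~zero
    denom = np.abs(1.0 - fh[nz]) ** 2
    S[nz] = r0 * (1.0 - np.abs(fh[nz]) ** 2) / denom
    return np.clip(S, 0.0, None)


def _transfer_branches(V, dv, D, F, P0_nodes, C, omegas, i_reset):
    """Reinjection and forcing branches of the modulated Fokker-Planck system."""
    E, G = _exp_factors(F / D, dv)
    nw = len(omegas)
    iw = 1j * omegas
    p_r = np.zeros(nw, dtype=complex)
    j_r = np.ones(nw, dtype=complex)
    p_e = np.zeros(nw, dtype=complex)
    j_e = np.zeros(nw, dtype=complex)
    for k in range(len(V) - 1):
        p_r_new = p_r * E[k] + (-j_r / D) * G[k]
        j_r_next = j_r + iw * dv * 0.5 * (p_r + p_r_new)
        P0_mid = 0.5 * (P0_nodes[k] + P0_nodes[k + 1])
        p_e_new = p_e * E[k] + ((-j_e + P0_mid / C) / D) * G[k]
        j_e_next = j_e + iw * dv * 0.5 * (p_e + p_e_new)
        p_r, j_r = p_r_new, j_r_next
        p_e, j_e = p_e_new, j_e_next
        if k + 1 == i_reset:
            j_r = j_r - 1.0  # reinjection of the modulated rate at the reset
    return j_r, j_e


def transfer_function(
    eff: EffectiveDiffusion,
    neuron: NeuronParams,
    freqs: np.ndarray,
    n: int = DEFAULT_N_GRID,
    gain_dI: float = 1e-4,
) -> np.ndarray:
    """Complex transfer function A(f) (Hz/nA) for injected sinusoidal current.

    The modulated Fokker-Planck system is decomposed into a reinjection
    branch and a forcing branch proportional to the stationary density; the
    zero-total-flux condition at the lower bound fixes the rate modulation.
    The ``f = 0`` entry is the static gain, computed as the symmetric finite
    difference of the steady-state rate with respect to a bias current
    (step ``gain_dI`` nA).
    """
    freqs = np.asarray(freqs, dtype=float)
    D = 0.5 * (eff.sigma / neuron.C) ** 2
    if D <= 0.0:
        raise FokkerPlanckError("transfer_function requires sigma > 0")
    V, dv, i_reset = _grid(eff, neuron, n)
    F = _drift_mid(V, eff)
    _, P0, _ = _steady_density(eff, neuron, n)
    out = np.zeros(len(freqs), dtype=complex)
    zero = freqs == 0.0
    if np.any(zero):
        out[zero] = _static_gain(eff, neuron, n, gain_dI)
    nz = ~zero
    if np.any(nz):
        omegas = 2.0 * math.pi * freqs[nz] * 1e-3
        j_r, j_e = _transfer_branches(V, dv, D, F, P0, neuron.C, omegas, i_reset)
        A = -(j_e / j_r) * 1e3  # kHz/nA -> Hz/nA
        if not np.all(np.isfinite(A)):
            bad = freqs[nz][~np.isfinite(A)][0]
            raise FokkerPlanckError(f"transfer-function solve diverged at f = {bad:g} Hz")
        out[nz] = A
    return out


def _static_gain(eff: EffectiveDiffusion, neuron: NeuronParams, n: int, dI: float) -> float:
    """d(rate)/d(bias current) in Hz/nA, by symmetric finite difference.

    A bias current I shifts the effective equilibrium potential by
    ``I / g_tot`` (1e3 mV per nA/nS).
    """
    dV = dI / eff.g_tot * 1e3  # mV
    hi = EffectiveDiffusion(eff.g_tot, eff.tau_eff, eff.V_inf + dV, eff.sigma)
    lo = EffectiveDiffusion(eff.g_tot, eff.tau_eff, eff.V_inf - dV, eff.sigma)
    return (steady_state_rate(hi, neuron, n) - steady_state_rate(lo, neuron, n)) / (2 * dI)


# ---------------------------------------------------------------------------
# convenience surfaces
# ---------------------------------------------------------------------------


def default_freq_grid(f_max: float = 2000.0) -> np.ndarray:
    """Master frequency grid (Hz): dense and linear at low f, log-spaced above."""
    low = np.linspace(0.25, 50.0, 200)
    high = np.geomspace(50.0, f_max, 200)[1:]
    return np.concatenate(([0.0], low, high))


def spectral_response(
    eff: EffectiveDiffusion,
    neuron: NeuronParams,
    freqs: np.ndarray | None = None,
    n: int = DEFAULT_N_GRID,
) -> SpectralResponse:
    """Bundle r0, A(f) and S(f) for one state on a common frequency grid."""
    if freqs is None:
        freqs = default_freq_grid()
    freqs = np.asarray(freqs, dtype=float)
    r0 = steady_state_rate(eff, neuron, n)
    A = transfer_function(eff, neuron, freqs, n)
    S = power_spectrum(eff, neuron, freqs, n)
    return SpectralResponse(freqs=freqs, A=A, S=S, r0=r0, sigma=eff.sigma)


def gain_curve(
    neuron: NeuronParams,
    drive: SynapticDrive,
    nu_E_grid: np.ndarray,
    n: int = DEFAULT_N_GRID,
) -> np.ndarray:
    """Steady-state rate (Hz) as the excitatory input rate is varied.

    Inhibition and weights are held at the template's values, so this traces
    the conductance-model rate curve whose slope at the operating point is
    the firing-rate gain.
    """
    from dataclasses import replace

    rates = np.empty(len(nu_E_grid))
    for i, nu_E in enumerate(np.asarray(nu_E_grid, dtype=float)):
        eff = effective_params(neuron, replace(drive, nu_E=nu_E))
        rates[i] = steady_state_rate(eff, neuron, n)
    return rates
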