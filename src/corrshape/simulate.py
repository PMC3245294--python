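"""Stochastic simulation of single LIF neurons and correlated pairs.

Two routes to the same pair statistics:

* :func:`simulate_pair_diffusion` — Euler-Maruyama integration of the
  diffusion-limit voltage equation, with the correlated white-noise
  construction ``xi_k = sqrt(1-c) xi_private + sqrt(c) xi_shared``.
* :func:`simulate_pair_shotnoise` — explicit Poisson synaptic events
  (delta or alpha conductance kernels), with the shared fraction realized
  by splitting each presynaptic population into a common stream of rate
  ``c nu`` and private streams of rate ``(1-c) nu``.

The shot-noise route validates the diffusion approximation; both share the
threshold/reset rule (end-of-step crossing detection, reset in the same
step) and the default timestep of 0.005 ms.

All simulator entry points are deterministic given (seed, dt, parameters).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numba
import numpy as np

from .model import NeuronParams, StateConfig, effective_params

__all__ = [
    "SpikeTrain",
    "SimResult",
    "simulate_pair_diffusion",
    "simulate_pair_shotnoise",
    "simulate_with_conductances",
    "summarize",
    "IntegrationError",
]

DEFAULT_DT = 0.005  # ms
_V_BLOWUP = 500.0  # mV; |V| beyond this aborts the integration
_MAX_RATE_GUESS = 0.6  # kHz; spike-buffer headroom


class IntegrationError(RuntimeError):
    pass


@dataclass(frozen=True)
class SpikeTrain:
    """Ordered spike times (ms) on [0, duration]."""

    times: np.ndarray
    duration: float

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", t)
        if t.size and (np.any(np.diff(t) <= 0) or t[0] < 0 or t[-1] > self.duration):
            raise ValueError("spike times must be strictly increasing within [0, duration]")

    @property
    def rate(self) -> float:
        """Mean firing rate in Hz."""
        return len(self.times) / self.duration * 1e3


@dataclass(frozen=True)
class SimResult:
    trains: tuple[SpikeTrain, ...]
    seed: int
    dt: float
    voltage: np.ndarray | None = None  # (n_neurons, n_samples), mV, subsampled
    voltage_times: np.ndarray | None = None
    current: np.ndarray | None = None  # summed synaptic current of neuron 0 (nA)

    @property
    def rates(self) -> list[float]:
        return [tr.rate for tr in self.trains]


def summarize(train: SpikeTrain) -> dict:
    """Rate (Hz) and ISI coefficient of variation of one spike train.

    With fewer than two spikes (no ISI) the CV is undefined: ``cv_isi`` is
    NaN and ``cv_defined`` False; no exception is raised.  The CV uses the
    sample (ddof=1) standard deviation.
    """
    rate = train.rate
    isi = np.diff(train.times)
    if isi.size >= 2:
        cv = float(np.std(isi, ddof=1) / np.mean(isi))
    elif isi.size == 1:
        cv = float("nan")
    else:
        cv = float("nan")
    return {"rate": rate, "cv_isi": cv, "cv_defined": math.isfinite(cv)}


@numba.njit(cache=True)
def _em_pair_kernel(tau, V_inf, beta_dt, c, V_th, V_r, V0, n_steps, dt, seed,
                    rec_stride, max_spikes):
    np.random.seed(seed)
    sc = math.sqrt(c)
    sp = math.sqrt(1.0 - c)
    V1 = V0
    V2 = V0
    t1 = np.empty(max_spikes)
    t2 = np.empty(max_spikes)
    n1 = 0
    n2 = 0
    n_rec = n_steps // rec_stride + 1
    volt = np.empty((2, n_rec))
    k_rec = 0
    status = 0
    for k in range(n_steps):
        if k % rec_stride == 0 and k_rec < n_rec:
            volt[0, k_rec] = V1
            volt[1, k_rec] = V2
            k_rec += 1
        s = np.random.standard_normal()
        e1 = sp * np.random.standard_normal() + sc * s
        e2 = sp * np.random.standard_normal() + sc * s
        V1 += dt * (-(V1 - V_inf) / tau) + beta_dt * e1
        V2 += dt * (-(V2 - V_inf) / tau) + beta_dt * e2
        t = (k + 1) * dt
        if V1 >= V_th:
            if n1 < max_spikes:
                t1[n1] = t
                n1 += 1
            V1 = V_r
        if V2 >= V_th:
            if n2 < max_spikes:
                t2[n2] = t
                n2 += 1
            V2 = V_r
        if abs(V1) > _V_BLOWUP or abs(V2) > _V_BLOWUP:
            status = 1
            break
    return t1[:n1], t2[:n2], volt[:, :k_rec], status


def simulate_pair_diffusion(
    state: StateConfig,
    c: float | None = None,
    duration: float = 10_000.0,
    dt: float = DEFAULT_DT,
    seed: int = 0,
    record_voltage: bool = False,
    voltage_stride: float = 0.1,
    bias_current: float = 0.0,
) -> SimResult:
    """Euler-Maruyama simulation of a pair in the diffusion limit.

    Both neurons follow the effective OU voltage equation of the state, with
    a fraction ``c`` of their white-noise input shared (default: the state's
    drive ``c``).  ``bias_current`` (nA) shifts the equilibrium potential by
    ``I/g_tot``.  Spikes are detected at end-of-step crossings and the
    voltage is reset within the same step.
    """
    if c is None:
        c = state.drive.c
    if not 0.0 <= c <= 1.0:
        raise ValueError(f"shared fraction c must lie in [0, 1], got {c}")
    eff = effective_params(state.neuron, state.drive)
    V_inf = eff.V_inf + bias_current / eff.g_tot * 1e3
    beta = eff.sigma / state.neuron.C
    n_steps = int(round(duration / dt))
    rec_stride = max(1, int(round(voltage_stride / dt))) if record_voltage else n_steps + 1
    max_spikes = int(duration * _MAX_RATE_GUESS) + 64
    t1, t2, volt, status = _em_pair_kernel(
        eff.tau_eff, V_inf, beta * math.sqrt(dt), c, state.neuron.V_th,
        state.neuron.V_r, state.neuron.E_L, n_steps, dt, seed, rec_stride, max_spikes,
    )
    if status != 0:
        raise IntegrationError(f"voltage diverged; dt = {dt} ms may be too coarse")
    trains = (SpikeTrain(t1, duration), SpikeTrain(t2, duration))
    kw = {}
    if record_voltage:
        kw["voltage"] = volt
        kw["voltage_times"] = np.arange(volt.shape[1]) * rec_stride * dt
    return SimResult(trains=trains, seed=seed, dt=dt, **kw)


@numba.njit(cache=True)
def _shot_pair_kernel(g_L, C, E_L, E_E, E_I, V_th, V_r, V0,
                      nu_E, nu_I, a_E, a_I, c, alpha, tau_sE, tau_sI,
                      I_bias, n_steps, dt, seed, max_spikes, rec_stride):
    """Poisson shot-noise pair; shared streams at rate c*nu, private at (1-c)*nu.

    For the delta kernel each event deposits charge a*(E_rev - V) directly;
    for the alpha kernel events feed a two-stage filter whose impulse
    response peaks at a after tau_s.
    """
    np.random.seed(seed)
    lam_sE = c * nu_E * dt
    lam_pE = (1.0 - c) * nu_E * dt
    lam_sI = c * nu_I * dt
    lam_pI = (1.0 - c) * nu_I * dt
    V = np.empty(2)
    V[0] = V0
    V[1] = V0
    yE = np.zeros(2)
    gE = np.zeros(2)
    yI = np.zeros(2)
    gI = np.zeros(2)
    wE = math.e * a_E  # alpha kernel: peak a_E at t = tau_s after the event
    wI = math.e * a_I
    t_out = np.empty((2, max_spikes))
    n_out = np.zeros(2, dtype=np.int64)
    n_rec = n_steps // rec_stride + 1
    current = np.empty(n_rec)
    k_rec = 0
    status = 0
    for k in range(n_steps):
        nsE = np.random.poisson(lam_sE)
        nsI = np.random.poisson(lam_sI)
        npE0 = np.random.poisson(lam_pE)
        npE1 = np.random.poisson(lam_pE)
        npI0 = np.random.poisson(lam_pI)
        npI1 = np.random.poisson(lam_pI)
        if k % rec_stride == 0 and k_rec < n_rec:
            # summed synaptic current of neuron 0 (nA); for the delta kernel
            # impulsive charge is spread over the step
            if alpha:
                current[k_rec] = (gE[0] * (E_E - V[0]) + gI[0] * (E_I - V[0])) * 1e-3
            else:
                current[k_rec] = ((nsE + npE0) * a_E * (E_E - V[0])
                                  + (nsI + npI0) * a_I * (E_I - V[0])) * 1e-3 / dt
            k_rec += 1
        for i in range(2):
            nE = nsE + (npE0 if i == 0 else npE1)
            nI = nsI + (npI0 if i == 0 else npI1)
            if alpha:
                yE[i] += wE * nE
                yI[i] += wI * nI
                dgE = (yE[i] - gE[i]) / tau_sE
                dyE = -yE[i] / tau_sE
                dgI = (yI[i] - gI[i]) / tau_sI
                dyI = -yI[i] / tau_sI
                dV = (-g_L * (V[i] - E_L) - gE[i] * (V[i] - E_E)
                      - gI[i] * (V[i] - E_I) + I_bias * 1e3) / C * 1e-3
                V[i] += dt * dV
                gE[i] += dt * dgE
                yE[i] += dt * dyE
                gI[i] += dt * dgI
                yI[i] += dt * dyI
            else:
                dV = (-g_L * (V[i] - E_L) + I_bias * 1e3) / C * 1e-3
                V[i] += dt * dV
                V[i] += (nE * a_E * (E_E - V[i]) + nI * a_I * (E_I - V[i])) / C * 1e-3
            if V[i] >= V_th:
                if n_out[i] < max_spikes:
                    t_out[i, n_out[i]] = (k + 1) * dt
                    n_out[i] += 1
                V[i] = V_r
            if abs(V[i]) > _V_BLOWUP:
                status = 1
        if status != 0:
            break
    return t_out[0, : n_out[0]], t_out[1, : n_out[1]], current[:k_rec], status


def simulate_pair_shotnoise(
    state: StateConfig,
    c: float | None = None,
    duration: float = 10_000.0,
    dt: float = DEFAULT_DT,
    seed: int = 0,
    bias_current: float = 0.0,
    record_current: bool = False,
    current_stride: float = 0.1,
) -> SimResult:
    """Explicit Poisson-synapse simulation of a correlated pair.

    The drive's kernel selects delta (impulse charge per event) or alpha
    (filtered conductance with peak ``a`` at lag ``tau_s``) synapses.  Shared
    input is realized by a common Poisson stream of rate ``c nu`` per
    population, so both neurons are statistically exchangeable and the
    summed-input correlation equals ``c``.
    """
    if c is None:
        c = state.drive.c
    if not 0.0 <= c <= 1.0:
        raise ValueError(f"shared fraction c must lie in [0, 1], got {c}")
    d = state.drive
    nrn = state.neuron
    n_steps = int(round(duration / dt))
    max_spikes = int(duration * _MAX_RATE_GUESS) + 64
    rec_stride = max(1, int(round(current_stride / dt))) if record_current else n_steps + 1
    t1, t2, current, status = _shot_pair_kernel(
        nrn.g_L, nrn.C, nrn.E_L, nrn.E_E, nrn.E_I, nrn.V_th, nrn.V_r, nrn.E_L,
        d.nu_E, d.nu_I, d.a_E, d.a_I, c, d.kernel == "alpha", d.tau_sE, d.tau_sI,
        bias_current, n_steps, dt, seed, max_spikes, rec_stride,
    )
    if status != 0:
        raise IntegrationError(f"voltage diverged; dt = {dt} ms may be too coarse")
    trains = (SpikeTrain(t1, duration), SpikeTrain(t2, duration))
    return SimResult(trains=trains, seed=seed, dt=dt,
                     current=current if record_current else None)


@numba.njit(cache=True)
def _lif_conductance_kernel(g_L, C, E_L, E_E, E_I, V_th, V_r, gE, gI, I_bias,
                            dt, max_spikes):
    V = E_L
    t_out = np.empty(max_spikes)
    n = 0
    for k in range(len(gE)):
        dV = (-g_L * (V - E_L) - gE[k] * (V - E_E) - gI[k] * (V - E_I)
              + I_bias * 1e3) / C * 1e-3
        V += dt * dV
        if V >= V_th:
            if n < max_spikes:
                t_out[n] = (k + 1) * dt
                n += 1
            V = V_r
    return t_out[:n]


def simulate_with_conductances(
    neuron: NeuronParams,
    g_E: np.ndarray,
    g_I: np.ndarray,
    dt: float,
    bias_current: float = 0.0,
) -> SpikeTrain:
    """Drive a LIF neuron with prescribed conductance traces (nS).

    This is the software analogue of a dynamic-clamp protocol: the stimulus
    is fully specified, so the response is deterministic given the neuron's
    parameters and bias current (nA).
    """
    if len(g_E) != len(g_I):
        raise ValueError("conductance traces must have equal length")
    duration = len(g_E) * dt
    max_spikes = int(duration * _MAX_RATE_GUESS) + 64
    times = _lif_conductance_kernel(
        neuron.g_L, neuron.C, neuron.E_L, neuron.E_E, neuron.E_I,
        neuron.V_th, neuron.V_r,
        np.ascontiguousarray(g_E, dtype=np.float64),
        np.ascontiguousarray(g_I, dtype=np.float64),
        bias_current, dt, max_spikes,
    )
    return SpikeTrain(times, duration)
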