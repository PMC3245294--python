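"""Feedforward propagation: correlation-shaped input to downstream readouts.

A population of N layer-2 conductance-LIF neurons receives balanced Poisson
input with a globally shared component (fraction ``c``), so any pair of
layer-2 neurons has the pairwise statistics of the two-neuron model.  Their
spikes converge through delta-function current synapses (voltage jump ``J``
mV per spike) onto a downstream LIF whose membrane time constant ``tau_d``
is set explicitly — a fast (3 ms) and a slow (20 ms) readout are compared on
identical upstream realizations.

Because the layer-2 rate is held at its calibrated value along the whole
low-to-high path, any change in downstream firing reflects the shaping of
upstream correlation, not a rate change: the fast readout is recruited by
the growing synchrony of the high state while the slow readout, sensitive
to long-timescale co-variation, disengages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numba
import numpy as np
import pandas as pd

from .calibrate import calibrate_nu_I
from .model import NeuronParams, StateConfig, SynapticDrive, effective_params
from .simulate import DEFAULT_DT, SpikeTrain, _V_BLOWUP

__all__ = [
    "FeedforwardConfig",
    "simulate_layer2",
    "drive_downstream",
    "calibrate_downstream_weight",
    "propagation_sweep",
]


@dataclass(frozen=True)
class FeedforwardConfig:
    """Layered-network layout: population size, sharing, readout timescales."""

    N: int = 100
    c: float = 0.1
    tau_fast: float = 3.0
    tau_slow: float = 20.0
    target_rate: float = 15.0
    downstream_rate: float = 5.0  # rate (Hz) the weight calibration equalizes at
    n_path: int = 8

    def __post_init__(self):
        if self.N < 2:
            raise ValueError("FeedforwardConfig.N must be >= 2")
        if not 0.0 <= self.c <= 1.0:
            raise ValueError("FeedforwardConfig.c must lie in [0, 1]")


@numba.njit(cache=True)
def _layer_chunk_kernel(V, priv, shared, tau, V_inf, beta_dt, sc, sp,
                        V_th, V_r, dt, t0, times, ids, n_in):
    n = n_in
    status = 0
    for k in range(priv.shape[0]):
        s = sc * shared[k]
        t = t0 + (k + 1) * dt
        for i in range(V.shape[0]):
            eta = sp * priv[k, i] + s
            V[i] += dt * (-(V[i] - V_inf) / tau) + beta_dt * eta
            if V[i] >= V_th:
                if n < len(times):
                    times[n] = t
                    ids[n] = i
                    n += 1
                V[i] = V_r
            if abs(V[i]) > _V_BLOWUP:
                status = 1
    return n, status


def simulate_layer2(
    state: StateConfig,
    N: int = 100,
    c: float = 0.1,
    duration: float = 20_000.0,
    dt: float = DEFAULT_DT,
    seed: int = 0,
) -> list[SpikeTrain]:
    """Simulate N exchangeable layer-2 neurons with a global shared input.

    Every neuron follows the state's diffusion-limit dynamics; the shared
    white-noise component (fraction ``c`` of the variance) is common to the
    whole population, so every pair is correlated like the two-neuron model.
    Noise is drawn in chunks from a seeded generator, so runs are
    reproducible for fixed (seed, dt, parameters).
    """
    eff = effective_params(state.neuron, state.drive)
    beta = eff.sigma / state.neuron.C
    n_steps = int(round(duration / dt))
    max_spikes = int(N * duration * 0.2) + 1024
    rng = np.random.default_rng(seed)
    V = np.full(N, state.neuron.E_L)
    times = np.empty(max_spikes)
    ids = np.empty(max_spikes, dtype=np.int64)
    n = 0
    chunk = 200_000
    done = 0
    while done < n_steps:
        m = min(chunk, n_steps - done)
        shared = rng.standard_normal(m)
        priv = rng.standard_normal((m, N))
        n, status = _layer_chunk_kernel(
            V, priv, shared, eff.tau_eff, eff.V_inf, beta * math.sqrt(dt),
            math.sqrt(c), math.sqrt(1.0 - c), state.neuron.V_th,
            state.neuron.V_r, dt, done * dt, times, ids, n,
        )
        if status != 0:
            raise RuntimeError("layer-2 integration diverged")
        done += m
    times, ids = times[:n], ids[:n]
    return [SpikeTrain(times[ids == i], duration) for i in range(N)]


@numba.njit(cache=True)
def _downstream_kernel(counts, tau_d, J, E_L, V_th, V_r, dt, max_spikes):
    V = E_L
    t_out = np.empty(max_spikes)
    n = 0
    for k in range(len(counts)):
        V += dt * (-(V - E_L) / tau_d)
        V += J * counts[k]
        if V >= V_th:
            if n < max_spikes:
                t_out[n] = (k + 1) * dt
                n += 1
            V = V_r
    return t_out[:n]


def drive_downstream(
    trains: list[SpikeTrain],
    tau_d: float,
    J: float,
    dt: float = DEFAULT_DT,
    neuron: NeuronParams | None = None,
    return_input: bool = False,
):
    """Feed upstream spike trains into a delta-synapse LIF readout.

    Each upstream spike increments the downstream voltage by ``J`` (mV); the
    membrane leaks with time constant ``tau_d``; threshold and reset match
    the canonical neuron.  Returns the downstream spike train, plus the
    per-step input spike-count trace when ``return_input`` is set.
    """
    if neuron is None:
        neuron = NeuronParams()
    duration = trains[0].duration
    n_steps = int(round(duration / dt))
    all_times = np.concatenate([tr.times for tr in trains])
    idx = np.minimum((all_times / dt).astype(np.int64), n_steps - 1)
    counts = np.bincount(idx, minlength=n_steps).astype(np.float64)
    max_spikes = int(duration * 0.6) + 64
    times = _downstream_kernel(
        counts, tau_d, J, neuron.E_L, neuron.V_th, neuron.V_r, dt, max_spikes
    )
    train = SpikeTrain(times, duration)
    return (train, counts) if return_input else train


def calibrate_downstream_weight(
    state: StateConfig,
    tau_d: float,
    config: FeedforwardConfig,
    duration: float = 20_000.0,
    dt: float = DEFAULT_DT,
    seed: int = 0,
    tol: float = 0.5,
) -> float:
    """Synaptic jump J (mV) giving the target downstream rate at one state.

    Bisection on J against a fixed upstream realization; run once at the
    path midpoint so both readout timescales fire at comparable rates given
    identical input.
    """
    trains = simulate_layer2(state, config.N, config.c, duration, dt, seed)
    lo, hi = 0.0, 2.0
    while drive_downstream(trains, tau_d, hi, dt, state.neuron).rate < config.downstream_rate:
        hi *= 2.0
        if hi > 50.0:
            raise RuntimeError("downstream weight calibration failed to bracket")
    for _ in range(30):
        mid = 0.5 * (lo + hi)
        r = drive_downstream(trains, tau_d, mid, dt, state.neuron).rate
        if abs(r - config.downstream_rate) < tol:
            return mid
        if r < config.downstream_rate:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def propagation_sweep(
    states: tuple[StateConfig, StateConfig],
    config: FeedforwardConfig | None = None,
    duration: float = 50_000.0,
    dt: float = DEFAULT_DT,
    seed: int = 0,
    weights: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Downstream rates of fast and slow readouts along the low-to-high path.

    The path interpolates ``nu_E`` between the two states' values over
    ``config.n_path`` points, re-balancing ``nu_I`` at each point so layer 2
    stays at its calibrated rate.  Both readouts consume the identical
    upstream realization at every point.  Returns a DataFrame with columns
    ``nu_E, nu_I, layer2_rate, rate_fast, rate_slow``.
    """
    if config is None:
        config = FeedforwardConfig()
    low, high = states
    nu_E_path = np.geomspace(low.drive.nu_E, high.drive.nu_E, config.n_path)
    path = []
    for nu_E in nu_E_path:
        template = replace(low.drive, nu_E=float(nu_E))
        nu_I = calibrate_nu_I(low.neuron, template, config.target_rate)
        path.append(StateConfig("path", replace(template, nu_I=nu_I), low.neuron))
    if weights is None:
        mid_state = path[config.n_path // 2]
        J_fast = calibrate_downstream_weight(mid_state, config.tau_fast, config, seed=seed + 901)
        J_slow = calibrate_downstream_weight(mid_state, config.tau_slow, config, seed=seed + 901)
    else:
        J_fast, J_slow = weights
    rows = []
    for i, st in enumerate(path):
        trains = simulate_layer2(st, config.N, config.c, duration, dt, seed + i)
        mean_rate = float(np.mean([tr.rate for tr in trains]))
        r_fast = drive_downstream(trains, config.tau_fast, J_fast, dt, st.neuron).rate
        r_slow = drive_downstream(trains, config.tau_slow, J_slow, dt, st.neuron).rate
        rows.append((st.drive.nu_E, st.drive.nu_I, mean_rate, r_fast, r_slow))
    df = pd.DataFrame(rows, columns=["nu_E", "nu_I", "layer2_rate", "rate_fast", "rate_slow"])
    df.attrs["J_fast"] = J_fast
    df.attrs["J_slow"] = J_slow
    return df
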