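"""Model parameters and the diffusion approximation of balanced synaptic input.

A leaky integrate-and-fire (LIF) neuron receives excitatory and inhibitory
conductance input from Poisson presynaptic populations.  For high input rates
the summed synaptic current is well approximated by a Gaussian white-noise
(diffusion) process, turning the conductance-driven voltage equation into an
Ornstein-Uhlenbeck process with absorbing threshold:

    tau_eff dV/dt = -(V - V_inf) + (tau_eff/C) * sigma * xi(t)

where ``tau_eff = C / g_tot`` is the effective membrane time constant set by
the total (leak + synaptic) conductance, ``V_inf`` the conductance-weighted
equilibrium potential and ``sigma`` the white-noise intensity of the synaptic
current evaluated at a frozen reference potential (the multiplicative nature
of conductance noise is deliberately ignored).

Units are fixed repo-wide: mV, ms, nS, nF, nA, kHz.  With these, nS*mV = nA
and nF/nS = ms.  ``sigma`` carries units nA*sqrt(ms): the two-sided spectral
density of the synaptic current is sigma**2 (nA^2 ms).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "NeuronParams",
    "SynapticDrive",
    "EffectiveDiffusion",
    "StateConfig",
    "effective_params",
    "mix_correlated_noise",
    "canonical_states",
    "canonical_neuron",
    "ParameterError",
]


class ParameterError(ValueError):
    """Raised when a model parameter violates its physical constraints."""


@dataclass(frozen=True)
class NeuronParams:
    """Passive membrane and spiking parameters of one LIF neuron.

    Attributes
    ----------
    tau_m : float
        Intrinsic membrane time constant C/g_L (ms).
    E_L, E_E, E_I : float
        Leak, excitatory and inhibitory reversal potentials (mV).
    V_th, V_r : float
        Spike threshold and reset potential (mV).
    C : float
        Membrane capacitance (nF); the leak conductance is ``C / tau_m``.
    """

    tau_m: float = 20.0
    E_L: float = -60.0
    E_E: float = 0.0
    E_I: float = -80.0
    V_th: float = -50.0
    V_r: float = -60.0
    C: float = 0.2

    def __post_init__(self) -> None:
        if self.tau_m <= 0:
            raise ParameterError("NeuronParams.tau_m must be > 0")
        if self.C <= 0:
            raise ParameterError("NeuronParams.C must be > 0")
        if not self.V_r < self.V_th:
            raise ParameterError("NeuronParams: require V_r < V_th")
        if not (self.E_I <= self.E_L < self.V_th < self.E_E):
            raise ParameterError("NeuronParams: require E_I <= E_L < V_th < E_E")

    @property
    def g_L(self) -> float:
        """Leak conductance (nS)."""
        return self.C / self.tau_m * 1e3  # nF/ms -> uS; *1e3 -> nS


@dataclass(frozen=True)
class SynapticDrive:
    """Poisson presynaptic drive defining one input state.

    ``a_E``/``a_I`` are per-event conductance amplitudes: for the ``delta``
    kernel they are the impulse *area* (nS*ms); for the ``alpha`` kernel they
    are the kernel *peak* g_max (nS) of ``g(t) = g_max (t/tau_s) e^{1-t/tau_s}``.
    ``c`` is the fraction of input fluctuations shared between the two neurons
    of a pair.
    """

    nu_E: float
    nu_I: float
    a_E: float
    a_I: float
    kernel: str = "delta"
    tau_sE: float = 6.0
    tau_sI: float = 8.0
    c: float = 0.0

    def __post_init__(self) -> None:
        if self.nu_E < 0 or self.nu_I < 0:
            raise ParameterError("SynapticDrive rates must be >= 0")
        if self.a_E < 0 or self.a_I < 0:
            raise ParameterError("SynapticDrive weights must be >= 0")
        if not 0.0 <= self.c <= 1.0:
            raise ParameterError(f"SynapticDrive.c must lie in [0, 1], got {self.c}")
        if self.kernel not in ("delta", "alpha"):
            raise ParameterError(f"SynapticDrive.kernel must be 'delta' or 'alpha', got {self.kernel!r}")
        if self.kernel == "alpha" and (self.tau_sE <= 0 or self.tau_sI <= 0):
            raise ParameterError("alpha kernel requires tau_sE, tau_sI > 0")

    def event_areas(self) -> tuple[float, float]:
        """Time integral of a single synaptic event's conductance (nS*ms)."""
        if self.kernel == "delta":
            return self.a_E, self.a_I
        # alpha kernel with peak a: integral = e * a * tau_s
        return math.e * self.a_E * self.tau_sE, math.e * self.a_I * self.tau_sI


@dataclass(frozen=True)
class EffectiveDiffusion:
    """Derived parameters of the diffusion-limit voltage equation.

    g_tot : total mean conductance (nS); tau_eff : effective membrane time
    constant (ms); V_inf : effective equilibrium potential (mV); sigma :
    white-noise intensity of the synaptic current (nA*sqrt(ms)).
    """

    g_tot: float
    tau_eff: float
    V_inf: float
    sigma: float


@dataclass(frozen=True)
class StateConfig:
    """One input state: a neuron plus the Poisson drive it receives."""

    label: str
    drive: SynapticDrive
    neuron: NeuronParams = field(default_factory=NeuronParams)


def effective_params(neuron: NeuronParams, drive: SynapticDrive) -> EffectiveDiffusion:
    """Map Poisson shot-noise conductance input to its diffusion limit.

    The mean conductances add to the leak; the effective time constant is
    ``C / g_tot``; the equilibrium potential is the conductance-weighted mean
    of the reversal potentials; and the noise intensity is the shot-noise
    current variance with the conductance driving force frozen at ``V_inf``::

        sigma^2 = nu_E A_E^2 (E_E - V_inf)^2 + nu_I A_I^2 (E_I - V_inf)^2

    with ``A`` the per-event conductance area.  The map is purely algebraic;
    no large-rate condition is enforced.
    """
    g_L = neuron.g_L
    A_E, A_I = drive.event_areas()
    gbar_E = A_E * drive.nu_E  # nS*ms * kHz = nS
    gbar_I = A_I * drive.nu_I
    g_tot = g_L + gbar_E + gbar_I
    if g_tot <= 0:
        raise ParameterError("total conductance must be positive")
    tau_eff = neuron.C * 1e3 / g_tot  # nF/nS = s, so *1e3 -> ms
    V_inf = (g_L * neuron.E_L + gbar_E * neuron.E_E + gbar_I * neuron.E_I) / g_tot
    var = (
        drive.nu_E * A_E**2 * (neuron.E_E - V_inf) ** 2
        + drive.nu_I * A_I**2 * (neuron.E_I - V_inf) ** 2
    )
    sigma = math.sqrt(var) * 1e-3  # var in pA^2*ms (nS*mV = pA); sqrt -> pA*sqrt(ms) -> nA*sqrt(ms)
    return EffectiveDiffusion(g_tot=g_tot, tau_eff=tau_eff, V_inf=V_inf, sigma=sigma)


def mix_correlated_noise(
    sigma: float,
    c: float,
    seed: int | np.random.Generator,
    duration: float,
    dt: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Two discretized white-noise current traces with correlation ``c``.

    Each trace is ``sqrt(1-c)*xi_private + sqrt(c)*xi_shared`` scaled so a
    sample has variance ``sigma^2 / dt`` (the discretization of a white-noise
    current of intensity ``sigma^2``), independent of ``c``.  The shared term
    is common to both traces, so their correlation coefficient is ``c`` in
    expectation.
    """
    if not 0.0 <= c <= 1.0:
        raise ParameterError(f"shared fraction c must lie in [0, 1], got {c}")
    if dt <= 0:
        raise ParameterError("dt must be > 0")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n = int(round(duration / dt))
    scale = sigma / math.sqrt(dt)
    shared = rng.standard_normal(n)
    xi1 = math.sqrt(1.0 - c) * rng.standard_normal(n) + math.sqrt(c) * shared
    xi2 = math.sqrt(1.0 - c) * rng.standard_normal(n) + math.sqrt(c) * shared
    return scale * xi1, scale * xi2


# ---------------------------------------------------------------------------
# Canonical parameter set
#
# The two reference input states: excitation at 1.50 kHz (low) and 6.16 kHz
# (high), with inhibition balanced so that both states fire at 15 Hz.  The
# per-event conductance areas below were fixed once, by scanning (a_E, a_I)
# with the Fokker-Planck solver so that the two calibrated states reproduce
# the target spiking irregularity (ISI CV ~0.73 low, ~0.91 high) at the 15 Hz
# operating point.  See docs/methods.md.
# ---------------------------------------------------------------------------

CANONICAL_NU_E_LOW = 1.50  # kHz
CANONICAL_NU_E_HIGH = 6.16  # kHz
CANONICAL_TARGET_RATE = 15.0  # Hz
CANONICAL_A_E = 2.5  # nS*ms, delta-kernel event area (frozen by CV calibration)
CANONICAL_A_I = 1.0  # nS*ms

_canonical_cache: dict[tuple, tuple[StateConfig, StateConfig]] = {}


def canonical_neuron() -> NeuronParams:
    """The repo's canonical LIF membrane parameter set."""
    return NeuronParams()


def canonical_states(c: float = 0.0) -> tuple[StateConfig, StateConfig]:
    """The canonical low/high balanced states, inhibition calibrated to 15 Hz.

    The inhibitory rate of each state is found by the calibration module
    (bisection on the Fokker-Planck steady-state rate) and cached; both states
    therefore produce the same 15 Hz output rate within solver tolerance.
    ``c`` sets the shared-input fraction stored in the returned drives.
    """
    key = (CANONICAL_A_E, CANONICAL_A_I, c)
    if key not in _canonical_cache:
        from .calibrate import calibrate_nu_I

        neuron = canonical_neuron()
        states = []
        for label, nu_E in (("low", CANONICAL_NU_E_LOW), ("high", CANONICAL_NU_E_HIGH)):
            template = SynapticDrive(nu_E=nu_E, nu_I=0.0, a_E=CANONICAL_A_E, a_I=CANONICAL_A_I, c=c)
            nu_I = calibrate_nu_I(neuron, template, target_rate=CANONICAL_TARGET_RATE)
            states.append(StateConfig(label=label, drive=replace(template, nu_I=nu_I), neuron=neuron))
        _canonical_cache[key] = (states[0], states[1])
    return _canonical_cache[key]
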