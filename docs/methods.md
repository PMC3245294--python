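# Methods

## Model

Each neuron is a leaky integrate-and-fire (LIF) unit receiving excitatory
and inhibitory conductance input from Poisson presynaptic populations:

    C dV/dt = -g_L (V - E_L) - g_E(t) (V - E_E) - g_I(t) (V - E_I) + I_bias

with a spike emitted and `V -> V_r` whenever `V >= V_th`.  The synaptic
conductances are shot-noise processes: each presynaptic event adds either a
delta impulse of area `a` (nS·ms) or an alpha waveform
`g_max (t/tau_s) e^{1-t/tau_s}` with peak `g_max`.

For high input rates the summed synaptic current is replaced by its
diffusion limit.  Writing `g_tot = g_L + a_E nu_E + a_I nu_I` (per-event
areas times rates), the voltage obeys an Ornstein–Uhlenbeck process with
absorbing threshold,

    dV/dt = -(V - V_inf)/tau_eff + (sigma/C) xi(t),

where `tau_eff = C/g_tot` is the effective membrane time constant,
`V_inf` the conductance-weighted equilibrium potential, and

    sigma^2 = nu_E A_E^2 (E_E - V_inf)^2 + nu_I A_I^2 (E_I - V_inf)^2

the white-noise intensity of the current with the multiplicative driving
terms frozen at `V_inf` (`A` = per-event conductance area).  Freezing at
`V_inf` is a modelling choice; the shot-noise simulator, which keeps the
multiplicative structure, is used to validate it.

For a pair of neurons, a fraction `c` of the input fluctuations is shared:
`xi_i = sqrt(1-c) xi_private,i + sqrt(c) xi_shared`, which leaves each
neuron's marginal statistics (and hence its firing rate) independent of `c`
while the input correlation coefficient equals `c`.

### Units

mV, ms, nS, nF, nA, kHz throughout (so nS·mV = pA and `C/g` in seconds is
converted once).  `sigma` carries nA·sqrt(ms): the two-sided spectral
density of the current noise is `sigma^2` in nA²·ms.  Public frequency axes
are in Hz, rates in Hz.

## Canonical parameter set

The two reference states fix the excitatory rate (1.50 kHz low, 6.16 kHz
high) and calibrate the inhibitory rate so each state fires at 15 Hz.  The
membrane constants are `tau_m = 20 ms`, `C = 0.2 nF` (`g_L = 10 nS`),
`E_L = V_r = -60 mV`, `E_E = 0 mV`, `E_I = -80 mV`, `V_th = -50 mV`, delta
kernels with per-event areas `a_E = 2.5` and `a_I = 1.0 nS·ms`.  The two
weights were fixed once by scanning `(a_E, a_I)` with the deterministic
Fokker–Planck solver so that the calibrated states reproduce the target
interspike-interval irregularity (CV 0.73 low, 0.91 high) at the 15 Hz
operating point.  The resulting state shift — `tau_eff` 10.8 → 3.4 ms and
`sigma` 0.17 → 0.37 nA·sqrt(ms), with `V_inf` moving < 3 mV — is the
high-conductance transition the model is built to study.

## Fokker–Planck threshold integration

All deterministic statistics come from integrating the Fokker–Planck
equation of the OU-with-threshold process downward in voltage from `V_th`
("threshold integration"), treating drift as constant within each grid step
and using the exact exponential update (stable for stiff, low-noise
parameters).

* **Steady state.**  Unit flux above the reset, zero below; the rate is the
  reciprocal of the density's normalization mass.
* **First-passage-time (ISI) transform.**  Two branches of the
  frequency-domain homogeneous system are integrated down to the lower
  bound, one started at threshold and one at the reset; the ratio of their
  fluxes at the bound is the Fourier transform `fhat(f)` of the ISI
  density.  This form retains sub-reset excursions, which matter because
  the lower bound lies well below the reset.  Expanding both branches to
  second order in frequency yields the ISI mean and CV in closed form.
* **Power spectrum.**  Renewal relation
  `S(f) = r0 (1 - |fhat|^2)/|1 - fhat|^2`; the singular `f = 0` entry is
  replaced by its analytic limit `r0 CV^2`.
* **Transfer function.**  The current-modulated system is decomposed into a
  reinjection branch and a forcing branch proportional to the stationary
  density; the zero-flux condition at the lower bound fixes the complex
  rate modulation `A(f)` (Hz/nA).  At `f = 0` the modulation system
  degenerates, so the static gain is computed as a symmetric finite
  difference of the steady-state rate with respect to a bias current; tests
  verify the modulated solve joins this value continuously as `f -> 0`.

Numerical choices: uniform voltage grid of 4096 points with the reset
snapped onto a node; lower bound `min(V_r, V_inf) - 10 sigma_V` (stationary
standard deviations), floored at `E_I - 10 mV` — an adaptive bound is
needed because the homogeneous solution grows like
`exp((V - V_inf)^2 / 2 sigma_V^2)` and a fixed deep bound overflows for
small noise; the truncation error of the adaptive bound is ~e^-50.  An
infinite normalization mass (mean first passage beyond float range) is
reported as a zero rate rather than an error.

The solver was validated against independent machinery: the deterministic
LIF closed form (1e-8 relative), stable Siegert-type quadrature for the
first two FPT moments (<5e-3 relative), empirical ISI characteristic
functions and a perturbed simulation with an injected sinusoid (3 SE).

## Correlation theory and estimators

The windowed spike-count correlation `rho_T` is the Pearson correlation of
the two neurons' counts in disjoint windows of length `T`.  For weak input
correlation the linear-response prediction is

    rho_T = c sigma^2 ∫ K_T(f) |A(f)|^2 df / ∫ K_T(f) S(f) df ,

where `K_T(f) = sin^2(pi f T)/(pi f)^2` is the Fourier transform of the
triangular count-window kernel: low-pass for large `T` (only the static
gain matters), flat for small `T` (all frequencies contribute, so the
high-frequency transfer sets synchrony).  Integrals are evaluated per
window on a grid fine enough to resolve the kernel's `1/T` oscillation
(40 points per lobe), with the spectral quantities interpolated from a
master grid reaching 2 kHz; the truncated tail is negligible because
`K_T |A|^2` decays faster than `1/f^2` and `S - r0` vanishes.

Estimators: `rho_T` uses disjoint windows with delete-one jackknife over 20
contiguous blocks for standard errors; the cross-correlogram is a
mean-subtracted pair-rate histogram with bins centered on zero lag;
coherence is Welch-averaged (2 s Hann segments, 1 ms bins) magnitude
coherence (RMS).  The high/low "shaping ratio" masks windows whose
baseline correlation is indistinguishable from zero and locates crossings
of 1 by linear interpolation.

Two controls isolate the mechanism: a current-based model (same
`sigma` shift, `tau_eff` pinned at `tau_m`, mean input recalibrated to
15 Hz) and a purely linear first-order filter, whose ratio is identically 1
because a linear system's output spectrum is `sigma^2 |A|^2` and the input
amplitude cancels.

## Simulators

Euler–Maruyama at the reference step `dt = 0.005 ms`, with end-of-step
threshold detection and same-step reset.  Discrete threshold detection
misses some continuous-time crossings, biasing rates low by roughly 1% (low
state) to 3% (high state) relative to the Fokker–Planck value; tests that
compare simulation with the deterministic calibration allow for this
documented bias on top of Monte-Carlo error, and no threshold-shift
correction is applied so the scheme remains plain Euler–Maruyama.

The shot-noise simulator draws Poisson event counts per step (common stream
of rate `c·nu`, private streams of `(1-c)·nu`) and applies delta impulses
or alpha-filter updates; it validates the diffusion limit (rates within
10%, matching shaping ratios within 15%).

The feedforward model runs N = 100 layer-2 neurons with one global shared
noise component and feeds their spikes through delta current synapses
(voltage jump `J` per spike) into a downstream LIF with its membrane time
constant set explicitly (3 ms vs 20 ms readouts).  `J` per readout is
calibrated once, at the midpoint of the low-to-high path, to a common
downstream rate (default 5 Hz), preserving "comparable rates given
identical input" without the unrecoverable published weights.

## Emulated dynamic-clamp experiment

Virtual cells are LIF neurons with a membrane set emulating layer-2/3
pyramidal recordings — rest −70 mV, inhibitory reversal at rest (shunting
inhibition), threshold −35 mV — because the protocol's stimulus (alpha
conductances, peak 1 nS, tau 6/8 ms, equal excitatory and inhibitory
Poisson rates of 3 kHz low / 7.5 kHz high) must remain slightly
subthreshold so that a constant bias current recruits sparse firing.  The
threshold was set so the unjittered cell reaches the protocol's 4–6 Hz band
with biases near 0.3 (low state) and 0.6 nA (high state); with the ±10%
per-cell jitter applied to leak conductance and threshold distance, the
bias search spans 0.05–1.5 nA, and cells that cannot reach the band are
excluded, mirroring experimental cell selection.  Bias is calibrated per
cell and per state on 32 calibration trials (the shared stimulus component
makes calibration noise common across cells, so short calibrations would
bias the whole population's rates together).

Stimuli are stationary: each trial's Poisson streams are warmed up by one
kernel length before the 4 s window, since the onset ramp of a convolution
from silence is common to all cells and would masquerade as input
correlation.  Within a trial the common component is frozen across cells
and redrawn across trials.  Per pair, `rho_T` pools within-trial count
deviations after subtracting each trial's own mean (removing slow
excitability drift); the short-vs-long window comparison across pairs uses
a one-sided paired t-test with a Wilcoxon companion.

## Synthetic data: what it does and does not emulate

All inputs are generated.  The generators reproduce the statistical design
of the study — Poisson presynaptic populations, balanced calibration,
half-shared stimulus construction, trial structure, mild cell
heterogeneity — but not biological realism beyond it: no synaptic
depression, no dendrites, no spike-frequency adaptation, no measurement
noise, and heterogeneity is uniform ±10% rather than an empirical
distribution.  Passing tests therefore demonstrate the internal
consistency of theory, simulation and analysis under the model's
assumptions, not that a given real circuit behaves this way.

## Problem sizes

Defaults used by the test suite and the acceptance script: 200 s pair
simulations for rate/CV statistics (≈3000 ISIs per neuron), 300 s for
correlated-pair estimates at c = 0.1, 100–200 s for feedforward runs,
8 cells × 40 × 4 s trials for the emulated experiment, a 4096-point voltage
grid and a 2 kHz master frequency grid for the solver.  These sizes put
Monte-Carlo standard errors comfortably below the effects being measured
(e.g. rate SE ≈ 0.25 Hz at 200 s) while keeping any single computation in
the seconds-to-minutes range.

## Known limitations

* The diffusion theory ignores synaptic filtering and multiplicative
  noise; both approximations are only validated empirically at the
  canonical operating points.
* Linear-response `rho_T` is first order in `c`; deviations appear for
  c ≳ 0.3.
* With the canonical parameter set and the default shared fraction
  c = 0.1 for the layered network, the slow readout's rate decrease along
  the low-to-high path is a small effect (a few tenths of a Hz), so long
  simulations are needed to resolve it; the fast readout's increase is
  larger and robust.
* Euler–Maruyama rate bias (above) is visible when comparing simulation
  with Fokker-Planck calibration at the printed step size.
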