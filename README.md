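# corrshape

**How the rate of balanced synaptic input shapes the correlation between
neural spike trains.**

Pairs of cortical neurons receive overlapping synaptic input, and the
correlation between their spike trains changes with brain state even when
the amount of input overlap does not.  `corrshape` implements a complete
modelling pipeline for one mechanism of such modulation: raising the rate
of *balanced* excitatory and inhibitory conductance input increases a
neuron's total conductance, shortening its effective membrane time constant
`tau_eff = C/g_tot` and raising its input noise `sigma`, while calibrated
inhibition keeps the output rate fixed.  This redistributes the pair
correlation across timescales — **correlation shaping**: spike synchrony
(short counting windows) grows while long-timescale rate co-variation
shrinks.

The package is aimed at computational neuroscientists who want to simulate,
predict, or emulate these effects quantitatively.  It provides:

* **Model core** — conductance-LIF parameters, the diffusion approximation
  `(g_tot, tau_eff, V_inf, sigma)` of Poisson shot-noise input, and the
  correlated-noise construction `sqrt(1-c)·private + sqrt(c)·shared`.
* **Simulators** — Euler–Maruyama integration of the diffusion limit and an
  explicit Poisson-synapse (delta or alpha kernel) simulator, for single
  neurons, pairs, and populations (numba-accelerated).
* **Fokker–Planck engine** — threshold integration for the steady-state
  rate, ISI moments, the first-passage-time transform, the renewal power
  spectrum `S(f)`, and the linear-response transfer function `A(f)`.
* **Correlation pipeline** — estimators (windowed count correlation
  `rho_T`, cross-correlogram, coherence) and the linear-response theory

      rho_T = c·sigma² ∫K_T(f)|A(f)|² df / ∫K_T(f) S(f) df,

  with the shaping-ratio statistic, susceptibility fits, and current-based
  and linear controls.
* **Calibration** — balanced inhibition for a target rate and iso-rate
  curves in the `(nu_E, nu_I)` plane.
* **Feedforward network** — 100 correlated neurons converging on fast
  (3 ms) and slow (20 ms) LIF readouts, demonstrating timescale-selective
  propagation.
* **Dynamic-clamp emulation** — a fully synthetic version of a paired
  intracellular experiment (alpha-conductance stimuli, half shared across
  cells, bias-calibrated 4–6 Hz firing, trialwise pairwise analysis).

## Worked example

```
$ python examples/correlation_shaping.py
input correlation c = 0.1
T (ms)   rho_low   rho_high   high/low
    1.0    0.0059    0.0077     1.314
    3.7    0.0152    0.0185     1.215
    9.9    0.0285    0.0287     1.008
   50.7    0.0532    0.0367     0.689
  500.0    0.0627    0.0385     0.615

The ratio decreases with window size and crosses 1 once, at T = 10.2 ms: ...
```

Both states fire at 15 Hz and receive identically correlated input
(c = 0.1); only the balanced input *rate* differs (excitation 1.50 vs
6.16 kHz).  Yet at 1 ms windows the high state is ~31% more correlated
(more synchronous) and at 500 ms it is ~38% less correlated: the high
state trades rate co-variation for synchrony.  The mechanism is visible in
`examples/transfer_and_spectrum.py`: the high state's transfer function is
attenuated ~2.2× at low frequency (gain reduction) but much less at high
frequency, because its faster membrane tracks fast inputs.

Other examples: `single_neuron_states.py` (the two balanced operating
points), `iso_rate_calibration.py` (iso-rate curves), `feedforward_gating.py`
(propagation sweep), `dynamic_clamp_emulation.py` (synthetic experiment).

A thin CLI exposes the same operations
(`corrshape config|simulate|theory|calibrate|isorate|shape|feedforward|synth-experiment`),
each writing delimited tables plus a JSON manifest with the resolved
configuration and seed.

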