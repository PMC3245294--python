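"""Software emulation of the paired dynamic-clamp protocol.

The in-silico experiment mirrors a dynamic-clamp design: every "cell" is a
LIF neuron driven by alpha-function excitatory and inhibitory conductance
trains built from Poisson event times, plus a constant bias current tuned so
the balanced fluctuations produce a low cortical firing rate in both input
states.  Within each trial, half of each cell's input processes are drawn
from a pool common to all cells and half are private, giving a pairwise
input correlation of 0.5; the common stimulus is frozen across cells within
a trial and redrawn across trials.  Cells carry mild parameter
heterogeneity, emulating the pooling of distinct neurons.

The virtual cells use their own membrane set emulating layer-2/3 pyramidal
recordings: rest at -70 mV, inhibitory reversal at rest (shunting
inhibition), threshold -40 mV.  With equal excitatory and inhibitory Poisson
rates this keeps the summed synaptic drive slightly subthreshold in both
states, so a positive bias current in the protocol's range recruits sparse
firing — the regime the protocol is designed around.

The analysis computes, per unordered cell pair, the windowed spike-count
correlation in the low and high input-rate states, the high/low ratio curve,
and a paired comparison of the ratio at a short versus a long counting
window across pairs.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats
from scipy.signal import fftconvolve

from .model import NeuronParams
from .simulate import SpikeTrain, simulate_with_conductances

__all__ = [
    "ExperimentDesign",
    "EXPERIMENT_NEURON",
    "generate_stimulus_set",
    "run_virtual_cells",
    "pairwise_ratio_analysis",
    "pair_count_correlation",
    "run_experiment",
]

EXPERIMENT_NEURON = NeuronParams(
    tau_m=20.0, E_L=-70.0, E_E=0.0, E_I=-70.0, V_th=-35.0, V_r=-60.0, C=0.2
)


@dataclass(frozen=True)
class ExperimentDesign:
    """Protocol constants of the emulated dynamic-clamp experiment.

    Rates are per-state Poisson rates (kHz), identical for excitation and
    inhibition; conductance events are alpha functions with peak ``g_max``
    and timescales ``tau_sE``/``tau_sI``; ``shared_fraction`` of each cell's
    input processes is common to all cells within a trial.
    """

    n_cells: int = 8
    trials: int = 40
    trial_duration: float = 4000.0  # ms
    rate_low: float = 3.0  # kHz
    rate_high: float = 7.5  # kHz
    g_max_E: float = 1.0  # nS
    g_max_I: float = 1.0  # nS
    tau_sE: float = 6.0  # ms
    tau_sI: float = 8.0  # ms
    shared_fraction: float = 0.5
    bias_range: tuple[float, float] = (0.05, 1.5)  # nA, bias search span
    # The dynamic-clamp protocol reports cells needing 0.3-0.7 nA; the
    # unjittered virtual cell lands in that range, but with +-10% parameter
    # heterogeneity the search span must be wider for every cell to reach
    # the firing-rate band (real experiments select cells that fit).
    target_rate_band: tuple[float, float] = (4.0, 6.0)  # Hz
    dt: float = 0.05  # ms; stimulus and integration step
    heterogeneity: float = 0.10  # fractional jitter of g_L and V_th per cell

    def __post_init__(self):
        if self.n_cells < 2:
            raise ValueError("ExperimentDesign.n_cells must be >= 2")
        if self.trials < 1:
            raise ValueError("ExperimentDesign.trials must be >= 1")
        if not 0.0 <= self.shared_fraction <= 1.0:
            raise ValueError("ExperimentDesign.shared_fraction must lie in [0, 1]")

    def rate(self, state: str) -> float:
        if state not in ("low", "high"):
            raise ValueError("state must be 'low' or 'high'")
        return self.rate_low if state == "low" else self.rate_high


def _alpha_kernel(tau_s: float, g_max: float, dt: float) -> np.ndarray:
    """Sampled alpha conductance g(t) = g_max (t/tau_s) exp(1 - t/tau_s)."""
    t = np.arange(0.0, 10.0 * tau_s, dt)
    return g_max * (t / tau_s) * np.exp(1.0 - t / tau_s)


def generate_stimulus_set(
    design: ExperimentDesign,
    state: str,
    seed: int,
    trials: int | None = None,
) -> np.ndarray:
    """Per-cell, per-trial conductance stimuli for one state.

    Returns an array of shape ``(n_cells, trials, 2, n_samples)`` (the third
    axis is excitatory/inhibitory, nS).  For each trial one common Poisson
    process per population (rate ``shared_fraction * nu``) is convolved with
    the alpha kernel and delivered identically to every cell, on top of a
    private process (rate ``(1 - shared_fraction) * nu``) per cell; the
    correlation between two cells' summed inputs is ``shared_fraction`` in
    expectation.
    """
    rng = np.random.default_rng(seed)
    nu = design.rate(state)
    dt = design.dt
    n = int(round(design.trial_duration / dt))
    trials = design.trials if trials is None else trials
    kE = _alpha_kernel(design.tau_sE, design.g_max_E, dt)
    kI = _alpha_kernel(design.tau_sI, design.g_max_I, dt)
    c = design.shared_fraction
    out = np.empty((design.n_cells, trials, 2, n), dtype=np.float32)
    pad = max(len(kE), len(kI))  # warm-up: drop the onset ramp so every
    # trial's conductance is statistically stationary from its first sample

    def conv(rate, kernel):
        events = rng.poisson(rate * dt, size=n + pad).astype(float)
        return fftconvolve(events, kernel)[pad : pad + n]

    for trial in range(trials):
        common_E = conv(c * nu, kE)
        common_I = conv(c * nu, kI)
        for cell in range(design.n_cells):
            out[cell, trial, 0] = common_E + conv((1 - c) * nu, kE)
            out[cell, trial, 1] = common_I + conv((1 - c) * nu, kI)
    return out


def _heterogeneous_cells(design: ExperimentDesign, seed: int) -> list[NeuronParams]:
    """Per-cell parameter jitter, fixed per cell across trials and states."""
    rng = np.random.default_rng(seed)
    base = EXPERIMENT_NEURON
    cells = []
    for _ in range(design.n_cells):
        if design.heterogeneity > 0:
            f_g = 1.0 + design.heterogeneity * (2 * rng.random() - 1)
            f_t = 1.0 + design.heterogeneity * (2 * rng.random() - 1)
        else:
            f_g = f_t = 1.0
        # jitter leak conductance via tau_m (C fixed) and threshold distance
        cells.append(
            replace(
                base,
                tau_m=base.tau_m / f_g,
                V_th=base.E_L + (base.V_th - base.E_L) * f_t,
            )
        )
    return cells


def _rate_on_stimuli(neuron, stimuli, design, bias, n_trials) -> float:
    counts = 0
    used = min(n_trials, stimuli.shape[0])
    for trial in range(used):
        tr = simulate_with_conductances(
            neuron, stimuli[trial, 0].astype(np.float64),
            stimuli[trial, 1].astype(np.float64), design.dt, bias
        )
        counts += len(tr.times)
    return counts / (used * design.trial_duration) * 1e3


def _calibrate_bias(
    neuron: NeuronParams,
    stimuli: np.ndarray,
    design: ExperimentDesign,
    n_cal_trials: int = 32,
) -> float | None:
    """Bias current (nA) placing the cell's rate inside the target band.

    Bisection over the protocol's bias range on calibration trials from one
    state; returns None (flagged cell, excluded) if the band is unreachable
    within the range — the software analogue of dropping a cell whose
    excitability does not suit the protocol.
    """
    lo, hi = design.bias_range
    band_lo, band_hi = design.target_rate_band
    target = 0.5 * (band_lo + band_hi)

    def rate(bias):
        return _rate_on_stimuli(neuron, stimuli, design, bias, n_cal_trials)

    if rate(hi) < band_lo or rate(lo) > band_hi:
        return None
    for _ in range(14):
        mid = 0.5 * (lo + hi)
        if rate(mid) < target:
            lo = mid
        else:
            hi = mid
    mid = 0.5 * (lo + hi)
    return mid if band_lo <= rate(mid) <= band_hi else None


def run_virtual_cells(
    stimuli: np.ndarray,
    design: ExperimentDesign,
    seed: int,
    bias: dict[int, float] | None = None,
) -> tuple[dict[int, list[SpikeTrain]], dict[int, float]]:
    """Simulate every virtual cell on its stimulus set.

    ``stimuli`` is the array from :func:`generate_stimulus_set`.  If ``bias``
    is not supplied, each cell's bias current is calibrated on its own
    stimuli.  Returns ``(trains, bias)``: per-cell lists of per-trial spike
    trains and the bias currents used.  Cells whose bias search fails are
    excluded (absent from the result), mirroring experimental practice.
    """
    cells = _heterogeneous_cells(design, seed)
    trains: dict[int, list[SpikeTrain]] = {}
    biases: dict[int, float] = {}
    for i, neuron in enumerate(cells):
        if bias is not None:
            if i not in bias:
                continue
            b = bias[i]
        else:
            b = _calibrate_bias(neuron, stimuli[i], design)
        if b is None:
            continue
        biases[i] = b
        trains[i] = [
            simulate_with_conductances(
                neuron, stimuli[i, t, 0].astype(np.float64),
                stimuli[i, t, 1].astype(np.float64), design.dt, b
            )
            for t in range(stimuli.shape[1])
        ]
    return trains, biases


def pair_count_correlation(
    trialsA: list[SpikeTrain],
    trialsB: list[SpikeTrain],
    windows: np.ndarray,
) -> np.ndarray:
    """rho_T for one cell pair from trial-structured data.

    Counts are taken in disjoint T-windows within each trial; each trial's
    own mean count is subtracted per cell before pooling deviations across
    trials (removing slow across-trial excitability drift), and the Pearson
    correlation of the pooled deviations is returned per window.
    """
    windows = np.asarray(windows, dtype=float)
    out = np.full(len(windows), np.nan)
    for i, T in enumerate(windows):
        devA, devB = [], []
        for ta, tb in zip(trialsA, trialsB):
            n_bins = int(ta.duration // T)
            if n_bins < 2:
                continue
            a = np.bincount(
                np.minimum((ta.times / T).astype(int), n_bins - 1), minlength=n_bins
            )[:n_bins].astype(float)
            b = np.bincount(
                np.minimum((tb.times / T).astype(int), n_bins - 1), minlength=n_bins
            )[:n_bins].astype(float)
            devA.append(a - a.mean())
            devB.append(b - b.mean())
        if not devA:
            continue
        a = np.concatenate(devA)
        b = np.concatenate(devB)
        if a.std() > 0 and b.std() > 0:
            out[i] = float(np.dot(a, b) / math.sqrt(np.dot(a, a) * np.dot(b, b)))
    return out


def pairwise_ratio_analysis(
    trains_low: dict[int, list[SpikeTrain]],
    trains_high: dict[int, list[SpikeTrain]],
    windows: np.ndarray,
    short_T: float = 2.0,
    long_T: float = 200.0,
) -> dict:
    """Population ratio curve and paired short-vs-long comparison.

    For every unordered pair of cells present in both states, rho_T is
    computed per state and the high/low ratio formed.  Returns the
    population-mean ratio curve with standard errors, the per-pair ratios at
    the short and long windows, and a one-sided paired t-test of
    ratio(short_T) > ratio(long_T) across pairs (Wilcoxon signed-rank as a
    distribution-free companion).  Pairs with zero spikes in a state are
    excluded and listed under ``excluded``.
    """
    windows = np.asarray(windows, dtype=float)
    cells = sorted(set(trains_low) & set(trains_high))
    ratios = []
    short_vals, long_vals = [], []
    excluded = []
    probe = np.array([short_T, long_T])
    for a, b in itertools.combinations(cells, 2):
        if (
            sum(len(t.times) for t in trains_low[a]) == 0
            or sum(len(t.times) for t in trains_low[b]) == 0
            or sum(len(t.times) for t in trains_high[a]) == 0
            or sum(len(t.times) for t in trains_high[b]) == 0
        ):
            excluded.append((a, b))
            continue
        rho_l = pair_count_correlation(trains_low[a], trains_low[b], windows)
        rho_h = pair_count_correlation(trains_high[a], trains_high[b], windows)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratios.append(rho_h / rho_l)
        pl = pair_count_correlation(trains_low[a], trains_low[b], probe)
        ph = pair_count_correlation(trains_high[a], trains_high[b], probe)
        short_vals.append(ph[0] / pl[0])
        long_vals.append(ph[1] / pl[1])
    ratios = np.asarray(ratios)
    short_vals = np.asarray(short_vals)
    long_vals = np.asarray(long_vals)
    n_pairs = len(short_vals)
    result = {
        "windows": windows,
        "mean_ratio": np.nanmean(ratios, axis=0) if n_pairs else np.full(len(windows), np.nan),
        "se_ratio": (
            np.nanstd(ratios, axis=0, ddof=1) / math.sqrt(n_pairs)
            if n_pairs > 1
            else np.full(len(windows), np.nan)
        ),
        "ratio_short": short_vals,
        "ratio_long": long_vals,
        "n_pairs": n_pairs,
        "excluded": excluded,
    }
    ok = np.isfinite(short_vals) & np.isfinite(long_vals)
    if ok.sum() >= 3:
        t, p = stats.ttest_rel(short_vals[ok], long_vals[ok], alternative="greater")
        result["t_stat"], result["p_value"] = float(t), float(p)
        try:
            _, pw = stats.wilcoxon(short_vals[ok], long_vals[ok], alternative="greater")
            result["wilcoxon_p"] = float(pw)
        except ValueError:
            result["wilcoxon_p"] = float("nan")
    return result


def run_experiment(
    design: ExperimentDesign,
    windows: np.ndarray,
    seed: int = 0,
    short_T: float = 2.0,
    long_T: float = 200.0,
    chunk: int = 10,
) -> dict:
    """End-to-end emulated experiment: stimuli, cells, pairwise analysis.

    Each cell's bias current is calibrated per state on short calibration
    stimulus sets (the target band must be reachable within the protocol's
    bias range in both states, or the cell is excluded), then the full trial
    blocks are generated and simulated in chunks to bound memory.
    """
    cells = _heterogeneous_cells(design, seed)
    bias: dict[str, dict[int, float]] = {}
    for k, state in enumerate(("low", "high")):
        cal = generate_stimulus_set(design, state, seed + 101 + k, trials=32)
        bias[state] = {}
        for i, neuron in enumerate(cells):
            b = _calibrate_bias(neuron, cal[i], design)
            if b is not None:
                bias[state][i] = b
    keep = sorted(set(bias["low"]) & set(bias["high"]))
    trains: dict[str, dict[int, list[SpikeTrain]]] = {}
    for k, state in enumerate(("low", "high")):
        state_bias = {i: bias[state][i] for i in keep}
        per_cell: dict[int, list[SpikeTrain]] = {i: [] for i in keep}
        done = 0
        block = 0
        while done < design.trials:
            m = min(chunk, design.trials - done)
            stim = generate_stimulus_set(design, state, seed + 1000 * (k + 1) + block, trials=m)
            got, _ = run_virtual_cells(stim, design, seed, bias=state_bias)
            for i in got:
                per_cell[i].extend(got[i])
            done += m
            block += 1
        trains[state] = per_cell
    res = pairwise_ratio_analysis(trains["low"], trains["high"], windows, short_T, long_T)
    res["trains"] = trains
    res["bias"] = bias
    return res
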