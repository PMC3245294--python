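"""Spike-train correlation estimators and the linear-response theory.

The central statistic is the windowed spike-count correlation

    rho_T = Cov(N1_T, N2_T) / sqrt(Var(N1_T) Var(N2_T)),

the Pearson correlation of the two neurons' spike counts in disjoint windows
of length T.  Small T probes spike-time synchrony; large T probes firing-rate
co-variation.  For weak input correlation c, linear-response theory predicts

    rho_T = c sigma^2 * Int K_T(f) |A(f)|^2 df / Int K_T(f) S(f) df

where A is the single-neuron transfer function, S the spike-train power
spectrum, sigma^2 the intensity of the (shared) white-noise input current and
K_T the Fourier transform of the triangular count-window kernel.  K_T selects
which frequencies of the neuron's response contribute at each counting
timescale: low-pass for large T, flat for small T.

Estimators (count correlation, cross-correlogram, coherence) operate on
simulated spike trains; the theory side consumes a
:class:`~corrshape.fokker_planck.SpectralResponse`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps

from . import fokker_planck as fp
from .fokker_planck import SpectralResponse
from .model import EffectiveDiffusion, StateConfig, effective_params
from .simulate import SpikeTrain

__all__ = [
    "CountCorrelation",
    "ShapingCurve",
    "SusceptibilityModel",
    "count_correlation",
    "cross_correlogram",
    "coherence",
    "triangle_weight",
    "spectral_window_integral",
    "rho_T_theory",
    "shaping_ratio",
    "susceptibility_fit",
    "current_based_control",
    "current_based_spectra",
    "linear_transfer_ratio",
    "default_windows",
]


def default_windows(n: int = 20) -> np.ndarray:
    """Logarithmic grid of counting windows, 1-500 ms."""
    return np.geomspace(1.0, 500.0, n)


@dataclass(frozen=True)
class CountCorrelation:
    """Windowed spike-count correlation over a grid of window sizes (ms)."""

    windows: np.ndarray
    rho: np.ndarray
    se: np.ndarray
    c_in: float | None = None

    def __post_init__(self):
        w = np.asarray(self.windows, dtype=float)
        if np.any(np.diff(w) <= 0):
            raise ValueError("windows must be strictly increasing")
        r = np.asarray(self.rho, dtype=float)
        finite = np.isfinite(r)
        if np.any(np.abs(r[finite]) > 1.0 + 1e-9):
            raise ValueError("|rho| must not exceed 1")


@dataclass(frozen=True)
class ShapingCurve:
    """High/low-state ratio of rho_T, with the window(s) where it crosses 1."""

    windows: np.ndarray
    ratio: np.ndarray
    se: np.ndarray
    crossings: np.ndarray


@dataclass(frozen=True)
class SusceptibilityModel:
    """Origin-constrained linear fit rho_T = S_T * c per window."""

    windows: np.ndarray
    slope: np.ndarray
    c_grid: np.ndarray
    residual_rms: np.ndarray


# ---------------------------------------------------------------------------
# estimators on spike trains
# ---------------------------------------------------------------------------


def _bin_counts(train: SpikeTrain, T: float) -> np.ndarray:
    n_bins = int(train.duration // T)
    idx = np.floor(train.times / T).astype(np.int64)
    idx = idx[idx < n_bins]
    return np.bincount(idx, minlength=n_bins).astype(float)


def count_correlation(
    trainA: SpikeTrain,
    trainB: SpikeTrain,
    windows: np.ndarray,
    c_in: float | None = None,
    n_jackknife: int = 20,
) -> CountCorrelation:
    """Pearson correlation of spike counts in disjoint windows of each length.

    Standard errors come from a delete-one jackknife over ``n_jackknife``
    contiguous blocks of windows.  A window with zero count variance in
    either train yields NaN (undefined) for that entry.
    """
    if trainA.duration != trainB.duration:
        raise ValueError("trains must share a duration")
    windows = np.asarray(windows, dtype=float)
    rho = np.full(len(windows), np.nan)
    se = np.full(len(windows), np.nan)
    for i, T in enumerate(windows):
        a = _bin_counts(trainA, T)
        b = _bin_counts(trainB, T)
        if a.std() == 0.0 or b.std() == 0.0 or len(a) < 2:
            continue
        rho[i] = _pearson(a, b)
        blocks = np.array_split(np.arange(len(a)), min(n_jackknife, len(a)))
        if len(blocks) >= 3:
            loo = []
            for blk in blocks:
                mask = np.ones(len(a), dtype=bool)
                mask[blk] = False
                if a[mask].std() > 0 and b[mask].std() > 0:
                    loo.append(_pearson(a[mask], b[mask]))
            if len(loo) >= 3:
                loo = np.asarray(loo)
                m = len(loo)
                se[i] = math.sqrt((m - 1) / m * np.sum((loo - loo.mean()) ** 2))
    return CountCorrelation(windows=windows, rho=rho, se=se, c_in=c_in)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    return float(np.dot(a, b) / math.sqrt(np.dot(a, a) * np.dot(b, b)))


def cross_correlogram(
    trainA: SpikeTrain,
    trainB: SpikeTrain,
    max_lag: float,
    bin: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean-subtracted cross-correlogram in Hz^2.

    Returns (lags, C) where ``C(tau)`` is the rate of (A, B) spike pairs at
    lag ``tau = t_B - t_A`` minus the chance level ``rate_A * rate_B``.
    Swapping the trains negates the lags.
    """
    if bin > max_lag:
        raise ValueError("bin must not exceed max_lag")
    n_bins = int(round(max_lag / bin))
    edges = (np.arange(-n_bins, n_bins + 2) - 0.5) * bin  # bins centered on lag 0
    tA, tB = trainA.times, trainB.times
    counts = np.zeros(2 * n_bins + 1)
    lo = np.searchsorted(tB, tA + edges[0])
    hi = np.searchsorted(tB, tA + edges[-1])
    for t, i0, i1 in zip(tA, lo, hi):
        if i1 > i0:
            counts += np.histogram(tB[i0:i1] - t, bins=edges)[0]
    duration = trainA.duration
    pair_rate = counts / (duration * bin)  # 1/ms^2
    chance = (len(tA) / duration) * (len(tB) / duration)
    lags = 0.5 * (edges[:-1] + edges[1:])
    return lags, (pair_rate - chance) * 1e6  # Hz^2


def coherence(
    trainA: SpikeTrain,
    trainB: SpikeTrain,
    freqs: np.ndarray | None = None,
    bin: float = 1.0,
    segment: float = 2000.0,
) -> tuple[np.ndarray, np.ndarray]:
    """RMS coherence between two spike trains.

    Trains are binned at ``bin`` ms and the magnitude coherence
    ``|Sxy| / sqrt(Sxx Syy)`` is estimated from Hann-tapered segments of
    length ``segment`` ms (Welch averaging).  Values lie in [0, 1] and the
    estimator is symmetric in its inputs.  If ``freqs`` (Hz) is given, the
    estimate is interpolated onto it.
    """
    x = _bin_counts(trainA, bin)
    y = _bin_counts(trainB, bin)
    fs = 1e3 / bin  # Hz
    nper = int(segment / bin)
    f, cxy = sps.coherence(x, y, fs=fs, nperseg=nper, window="hann")
    coh = np.sqrt(np.clip(cxy, 0.0, 1.0))
    if freqs is not None:
        coh = np.interp(np.asarray(freqs, dtype=float), f, coh)
        f = np.asarray(freqs, dtype=float)
    return f, coh


# ---------------------------------------------------------------------------
# linear-response theory
# ---------------------------------------------------------------------------


def triangle_weight(T: float, freqs: np.ndarray) -> np.ndarray:
    """Fourier transform of the triangular window kernel (T - |tau|)_+ (ms^2).

    ``K_T(f) = sin^2(pi f T) / (pi f)^2`` with ``K_T(0) = T^2``; zeros at
    integer multiples of 1/T.  For T -> infinity the normalized kernel
    concentrates at f = 0; for T -> 0, K_T/T^2 flattens, weighting all
    frequencies equally.
    """
    if T <= 0:
        raise ValueError("T must be > 0")
    f_khz = np.asarray(freqs, dtype=float) * 1e-3
    out = np.full(f_khz.shape, T * T)
    nz = f_khz != 0.0
    x = math.pi * f_khz[nz]
    out[nz] = np.sin(x * T) ** 2 / x**2
    return out


def spectral_window_integral(
    freqs: np.ndarray, values: np.ndarray, T: float, pts_per_lobe: int = 40
) -> float:
    """``Int_-inf^inf K_T(f) X(f) df`` for an even spectral quantity X.

    X is given on a (possibly coarse) master grid in Hz; it is linearly
    interpolated onto a grid fine enough to resolve the 1/T oscillation of
    K_T, and the integral is taken by the trapezoid rule over [0, f_max]
    and doubled.  With X in kHz-units and f in kHz the result is the
    count-window quadratic form (e.g. Var N_T for X = S).
    """
    freqs = np.asarray(freqs, dtype=float)
    f_max = freqs[-1]
    df = min(1.0 / (pts_per_lobe * T) * 1e3, 2.0)  # Hz
    grid = np.arange(0.0, f_max + df, df)
    X = np.interp(grid, freqs, values)
    K = triangle_weight(T, grid)
    return 2.0 * np.trapezoid(K * X, grid * 1e-3)  # df in kHz


def rho_T_theory(
    spec: SpectralResponse,
    sigma: float,
    c_in: float,
    windows: np.ndarray,
) -> CountCorrelation:
    """Linear-response prediction of the windowed count correlation.

    Both neurons are assumed statistically identical.  The cross-spectrum of
    the pair under shared white-noise current of intensity ``c sigma^2`` is
    ``c sigma^2 A A*``; weighting cross- and auto-spectra by the window
    kernel K_T yields rho_T.  Linear in ``c_in`` by construction.
    """
    if not 0.0 <= c_in <= 1.0:
        raise ValueError(f"c_in must lie in [0, 1], got {c_in}")
    windows = np.asarray(windows, dtype=float)
    if np.any(windows < 1e3 / spec.freqs[-1]):
        raise ValueError(
            "window shorter than the spectral grid can resolve; extend the "
            f"frequency grid beyond {spec.freqs[-1]:g} Hz"
        )
    A2 = np.abs(spec.A * 1e-3) ** 2  # (kHz/nA)^2
    S = spec.S * 1e-3  # kHz
    rho = np.empty(len(windows))
    for i, T in enumerate(windows):
        num = c_in * sigma**2 * spectral_window_integral(spec.freqs, A2, T)
        den = spectral_window_integral(spec.freqs, S, T)
        rho[i] = num / den
    return CountCorrelation(windows=windows, rho=rho, se=np.zeros(len(windows)), c_in=c_in)


def shaping_ratio(low: CountCorrelation, high: CountCorrelation) -> ShapingCurve:
    """Elementwise ratio rho_T(high)/rho_T(low) with propagated uncertainty.

    Entries where the low-state correlation is indistinguishable from zero
    (|rho| < 2 SE) are masked as NaN.  Window positions where the ratio
    crosses 1 are located by linear interpolation between grid points.
    """
    if not np.array_equal(low.windows, high.windows):
        raise ValueError("shaping ratio requires matched window grids")
    if low.c_in is not None and high.c_in is not None and low.c_in != high.c_in:
        raise ValueError("shaping ratio requires matched input correlation")
    rl, rh = low.rho.copy(), high.rho
    mask = np.isfinite(rl) & (np.abs(rl) > 2.0 * np.nan_to_num(low.se))
    ratio = np.where(mask, rh / np.where(mask, rl, 1.0), np.nan)
    rel = np.zeros(len(ratio))
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.sqrt((low.se / rl) ** 2 + (high.se / rh) ** 2)
    se = np.abs(ratio) * np.nan_to_num(rel)
    crossings = []
    g = ratio - 1.0
    for i in range(len(g) - 1):
        if np.isfinite(g[i]) and np.isfinite(g[i + 1]) and g[i] * g[i + 1] < 0:
            w = g[i] / (g[i] - g[i + 1])
            crossings.append(low.windows[i] + w * (low.windows[i + 1] - low.windows[i]))
    return ShapingCurve(
        windows=low.windows, ratio=ratio, se=se, crossings=np.asarray(crossings)
    )


def susceptibility_fit(
    results: dict[float, CountCorrelation],
) -> SusceptibilityModel:
    """Correlation susceptibility: slope of rho_T vs c through the origin.

    ``results`` maps each input correlation c to its measured (or predicted)
    count correlation on a common window grid.  The least-squares slope
    constrained through the origin is ``sum(c rho) / sum(c^2)`` per window.
    """
    cs = np.array(sorted(results))
    first = results[cs[0]]
    windows = first.windows
    R = np.vstack([results[c].rho for c in cs])  # (n_c, n_T)
    denom = np.sum(cs**2)
    slope = (cs[:, None] * R).sum(axis=0) / denom
    resid = R - cs[:, None] * slope[None, :]
    rms = np.sqrt(np.nanmean(resid**2, axis=0))
    return SusceptibilityModel(windows=windows, slope=slope, c_grid=cs, residual_rms=rms)


# ---------------------------------------------------------------------------
# controls
# ---------------------------------------------------------------------------


def current_based_spectra(
    states: tuple[StateConfig, StateConfig],
    target_rate: float = 15.0,
    freqs: np.ndarray | None = None,
    n: int = fp.DEFAULT_N_GRID,
) -> tuple[SpectralResponse, SpectralResponse]:
    """Spectral responses of the current-based control model.

    The control keeps the membrane time constant at its intrinsic value
    ``tau_m`` in both states (no conductance loading) while the noise
    intensity changes exactly as in the conductance states; the mean input
    (equilibrium potential) is re-adjusted per state so both fire at the
    target rate.  This isolates the role of the effective-time-constant
    shift in correlation shaping.
    """
    out = []
    for state in states:
        eff_g = effective_params(state.neuron, state.drive)
        g_L = state.neuron.g_L
        eff = EffectiveDiffusion(
            g_tot=g_L, tau_eff=state.neuron.tau_m, V_inf=state.neuron.E_L, sigma=eff_g.sigma
        )
        eff = _calibrate_v_inf(eff, state.neuron, target_rate, n)
        out.append(fp.spectral_response(eff, state.neuron, freqs, n))
    return out[0], out[1]


def _calibrate_v_inf(eff, neuron, target_rate, n):
    lo, hi = neuron.E_I, neuron.V_th + 20.0
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        r = fp.steady_state_rate(replace(eff, V_inf=mid), neuron, n)
        if abs(r - target_rate) < 1e-3:
            break
        if r < target_rate:
            lo = mid
        else:
            hi = mid
    return replace(eff, V_inf=mid)


def current_based_control(
    states: tuple[StateConfig, StateConfig],
    c_in: float = 0.1,
    windows: np.ndarray | None = None,
    target_rate: float = 15.0,
    n: int = fp.DEFAULT_N_GRID,
) -> ShapingCurve:
    """Shaping-ratio curve for the current-based (fixed tau) control model."""
    if windows is None:
        windows = default_windows()
    sl, sh = current_based_spectra(states, target_rate, n=n)
    low = rho_T_theory(sl, sl.sigma, c_in, windows)
    high = rho_T_theory(sh, sh.sigma, c_in, windows)
    return shaping_ratio(low, high)


def linear_transfer_ratio(
    windows: np.ndarray,
    tau: float = 20.0,
    gain: float = 1.0,
    amplitude_scale: float = 2.0,
    c_in: float = 0.1,
    f_max: float = 2000.0,
) -> np.ndarray:
    """High/low rho_T ratio for a purely linear (threshold-free) transfer.

    The "neuron" is a first-order low-pass filter ``A(f) = g/(1 + 2 pi i f
    tau)``; the high state only rescales the input amplitude by
    ``amplitude_scale``.  For a linear system the output spectrum is
    ``sigma^2 |A|^2``, so the amplitude cancels and rho_T = c at every T —
    the ratio is identically 1: a linear system cannot shape correlation.
    Computed numerically with the same window-integral machinery as the
    spiking theory.
    """
    windows = np.asarray(windows, dtype=float)
    freqs = np.concatenate(([0.0], np.geomspace(0.25, f_max, 400)))
    A2 = np.abs(gain / (1.0 + 2j * math.pi * freqs * 1e-3 * tau)) ** 2
    ratio = np.empty(len(windows))
    for i, T in enumerate(windows):
        num_int = spectral_window_integral(freqs, A2, T)
        rho_states = []
        for s in (1.0, amplitude_scale):
            sigma2 = s**2
            rho_states.append(c_in * sigma2 * num_int / (sigma2 * num_int))
        ratio[i] = rho_states[1] / rho_states[0]
    return ratio
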