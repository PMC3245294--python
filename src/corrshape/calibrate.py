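"""Balanced-input calibration: choosing inhibition to fix the output rate.

The defining constraint of the two reference states is that excitation is
set externally (1.50 kHz low, 6.16 kHz high) while the inhibitory Poisson
rate is chosen so that the neuron fires at a common target rate (15 Hz).
Calibration is performed against the deterministic Fokker-Planck rate and
verified against stochastic simulation in the test suite.  The same
machinery traces iso-rate curves in the (nu_E, nu_I) plane and runs the
rate-change comparison separating output-rate effects from state effects.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from . import fokker_planck as fp
from .model import NeuronParams, SynapticDrive, StateConfig, effective_params

__all__ = [
    "calibrate_nu_I",
    "calibrate_nu_E",
    "iso_rate_curve",
    "rate_change_comparison",
    "CalibrationError",
]


class CalibrationError(RuntimeError):
    """Raised when the requested target rate cannot be bracketed."""


def _rate_at(neuron: NeuronParams, drive: SynapticDrive, **kw) -> float:
    return fp.steady_state_rate(effective_params(neuron, drive), neuron, **kw)


def calibrate_nu_I(
    neuron: NeuronParams,
    drive: SynapticDrive,
    target_rate: float,
    tol: float = 0.01,
    n: int = fp.DEFAULT_N_GRID,
) -> float:
    """Inhibitory rate (kHz) at which the Fokker-Planck rate hits the target.

    Inhibition monotonically suppresses the rate, so the root is found by
    bisection after expanding an upper bracket.  Raises
    :class:`CalibrationError` with the achievable range if the target is not
    bracketed (e.g. the target exceeds the rate at ``nu_I = 0``).
    """
    lo = 0.0
    r_lo = _rate_at(neuron, replace(drive, nu_I=lo), n=n)
    if r_lo < target_rate - tol:
        raise CalibrationError(
            f"target {target_rate:g} Hz unreachable: rate at nu_I=0 is {r_lo:.3g} Hz"
        )
    if abs(r_lo - target_rate) <= tol:
        return 0.0
    hi = max(1.0, drive.nu_E)
    for _ in range(60):
        if _rate_at(neuron, replace(drive, nu_I=hi), n=n) < target_rate:
            break
        hi *= 2.0
    else:
        raise CalibrationError("could not bracket target rate from above")
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        r = _rate_at(neuron, replace(drive, nu_I=mid), n=n)
        if abs(r - target_rate) <= tol:
            return mid
        if r > target_rate:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def calibrate_nu_E(
    neuron: NeuronParams,
    drive: SynapticDrive,
    target_rate: float,
    tol: float = 0.01,
    n: int = fp.DEFAULT_N_GRID,
) -> float:
    """Excitatory rate (kHz) reaching the target with inhibition held fixed."""
    lo = 0.0
    r_lo = _rate_at(neuron, replace(drive, nu_E=lo), n=n)
    if r_lo > target_rate + tol:
        raise CalibrationError(
            f"target {target_rate:g} Hz below the rate {r_lo:.3g} Hz at nu_E=0"
        )
    hi = max(1.0, drive.nu_E)
    for _ in range(60):
        if _rate_at(neuron, replace(drive, nu_E=hi), n=n) > target_rate:
            break
        hi *= 2.0
    else:
        raise CalibrationError("could not bracket target rate from above")
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        r = _rate_at(neuron, replace(drive, nu_E=mid), n=n)
        if abs(r - target_rate) <= tol:
            return mid
        if r > target_rate:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def iso_rate_curve(
    neuron: NeuronParams,
    drive: SynapticDrive,
    target_rate: float,
    nu_E_grid: np.ndarray,
    tol: float = 0.01,
    n: int = fp.DEFAULT_N_GRID,
) -> pd.DataFrame:
    """Trace the (nu_E, nu_I) locus producing a fixed output rate.

    Returns a DataFrame with columns ``nu_E``, ``nu_I``, ``rate`` and
    ``feasible``; infeasible grid points (target above the rate achievable at
    zero inhibition) are flagged rather than fatal.  The curve's approximate
    linearity ("a balanced shift in input preserves output rate") can be
    summarized by ``df.attrs['r_squared']``, the R^2 of a straight-line fit
    through the feasible points.
    """
    rows = []
    for nu_E in np.asarray(nu_E_grid, dtype=float):
        template = replace(drive, nu_E=nu_E)
        try:
            nu_I = calibrate_nu_I(neuron, template, target_rate, tol=tol, n=n)
            rate = _rate_at(neuron, replace(template, nu_I=nu_I), n=n)
            rows.append((nu_E, nu_I, rate, True))
        except CalibrationError:
            rows.append((nu_E, np.nan, np.nan, False))
    df = pd.DataFrame(rows, columns=["nu_E", "nu_I", "rate", "feasible"])
    ok = df[df.feasible]
    if len(ok) >= 3:
        coef = np.polyfit(ok.nu_E, ok.nu_I, 1)
        resid = ok.nu_I - np.polyval(coef, ok.nu_E)
        ss_tot = np.sum((ok.nu_I - ok.nu_I.mean()) ** 2)
        df.attrs["r_squared"] = float(1.0 - np.sum(resid**2) / ss_tot) if ss_tot > 0 else 1.0
    return df


def rate_change_comparison(
    states: tuple[StateConfig, StateConfig],
    target_rates: tuple[float, ...] = (8.0, 15.0, 35.0),
    windows: np.ndarray | None = None,
    c: float = 0.1,
    ref_T: float = 100.0,
    n: int = fp.DEFAULT_N_GRID,
) -> pd.DataFrame:
    """Spike-count correlation curves at several output rates within each state.

    Within each state the output rate is moved to each target by changing
    ``nu_E`` only (``nu_I`` stays at the state's calibrated value), and the
    linear-response count correlation is evaluated.  Each curve is then
    multiplicatively scaled to match the middle-rate curve at the reference
    window ``ref_T`` (ms).  Rate changes within a state shift the overall
    magnitude of the correlation but barely its timescale profile, so the
    scaled within-state curves collapse while the low/high-state difference
    (the correlation shaping) survives scaling.
    """
    from .correlation import rho_T_theory

    if windows is None:
        windows = np.geomspace(1.0, 500.0, 20)
    windows = np.asarray(windows, dtype=float)
    mid = target_rates[len(target_rates) // 2]
    rows = []
    curves: dict[tuple[str, float], np.ndarray] = {}
    for state in states:
        for rate in target_rates:
            nu_E = calibrate_nu_E(state.neuron, state.drive, rate, n=n)
            drive = replace(state.drive, nu_E=nu_E)
            eff = effective_params(state.neuron, drive)
            spec = fp.spectral_response(eff, state.neuron, n=n)
            rho = rho_T_theory(spec, eff.sigma, c, windows).rho
            curves[(state.label, rate)] = rho
    for state in states:
        ref_curve = curves[(state.label, mid)]
        ref_val = np.interp(ref_T, windows, ref_curve)
        for rate in target_rates:
            rho = curves[(state.label, rate)]
            scale = ref_val / np.interp(ref_T, windows, rho)
            for T, r, rs in zip(windows, rho, rho * scale):
                rows.append((state.label, rate, T, r, rs))
    return pd.DataFrame(rows, columns=["state", "target_rate", "T", "rho", "rho_scaled"])
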