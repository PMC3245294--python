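"""Configuration files, spike-train tables, and run manifests.

All desk-scale artifacts are delimited text: spike trains as two-column TSV
(neuron_id, time_ms), tables as TSV via pandas, configuration as YAML, and a
JSON manifest per run recording the fully resolved configuration, seed and
package version so a run can be reproduced bitwise.
"""

from __future__ import annotations

import json
import time
from pathlib import Path

import numpy as np
import yaml

from .model import NeuronParams, StateConfig, SynapticDrive, ParameterError
from .simulate import SpikeTrain

__all__ = [
    "ConfigError",
    "default_config",
    "load_config",
    "save_config",
    "validate_config",
    "build_state",
    "write_spike_trains",
    "read_spike_trains",
    "write_manifest",
]


class ConfigError(ValueError):
    """Configuration problem, reporting the offending field path."""


_NEURON_FIELDS = {"tau_m", "E_L", "E_E", "E_I", "V_th", "V_r", "C"}
_DRIVE_FIELDS = {"nu_E", "nu_I", "a_E", "a_I", "kernel", "tau_sE", "tau_sI", "c"}


def default_config() -> dict:
    """The canonical configuration: membrane set plus low/high balanced states.

    ``nu_I: null`` requests calibration to ``target_rate_hz`` when the state
    is built.
    """
    from .model import CANONICAL_A_E, CANONICAL_A_I, CANONICAL_NU_E_HIGH, CANONICAL_NU_E_LOW

    neuron = NeuronParams()
    drive = {
        "a_E": CANONICAL_A_E,
        "a_I": CANONICAL_A_I,
        "kernel": "delta",
        "tau_sE": 6.0,
        "tau_sI": 8.0,
        "c": 0.1,
        "nu_I": None,
    }
    return {
        "neuron": {f: getattr(neuron, f) for f in sorted(_NEURON_FIELDS)},
        "states": {
            "low": {**drive, "nu_E": CANONICAL_NU_E_LOW},
            "high": {**drive, "nu_E": CANONICAL_NU_E_HIGH},
        },
        "target_rate_hz": 15.0,
        "simulation": {"duration_ms": 200_000.0, "dt_ms": 0.005, "seed": 0},
    }


def validate_config(config: dict) -> None:
    """Schema and bounds check; raises :class:`ConfigError` naming the field."""
    if not isinstance(config, dict):
        raise ConfigError("config root must be a mapping")
    for section in ("neuron", "states"):
        if section not in config:
            raise ConfigError(f"missing section '{section}'")
    unknown = set(config["neuron"]) - _NEURON_FIELDS
    if unknown:
        raise ConfigError(f"neuron.{unknown.pop()}: unknown field")
    try:
        NeuronParams(**config["neuron"])
    except (ParameterError, TypeError) as e:
        raise ConfigError(f"neuron: {e}") from e
    for label, entry in config["states"].items():
        unknown = set(entry) - _DRIVE_FIELDS
        if unknown:
            raise ConfigError(f"states.{label}.{unknown.pop()}: unknown field")
        for bounded, lo, hi in (("c", 0.0, 1.0),):
            v = entry.get(bounded)
            if v is not None and not lo <= v <= hi:
                raise ConfigError(f"states.{label}.{bounded}: {v} outside [{lo}, {hi}]")
        probe = dict(entry)
        if probe.get("nu_I") is None:
            probe["nu_I"] = 0.0
        try:
            SynapticDrive(**probe)
        except (ParameterError, TypeError) as e:
            raise ConfigError(f"states.{label}: {e}") from e
    sim = config.get("simulation", {})
    if sim.get("dt_ms", 0.005) <= 0:
        raise ConfigError("simulation.dt_ms: must be > 0")


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        config = yaml.safe_load(fh)
    validate_config(config)
    return config


def save_config(config: dict, path: str | Path) -> None:
    validate_config(config)
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)


def build_state(config: dict, label: str) -> StateConfig:
    """Materialize one state; a null inhibitory rate triggers calibration."""
    from .calibrate import calibrate_nu_I

    validate_config(config)
    if label not in config["states"]:
        raise ConfigError(f"states.{label}: no such state")
    neuron = NeuronParams(**config["neuron"])
    entry = dict(config["states"][label])
    if entry.get("nu_I") is None:
        entry["nu_I"] = 0.0
        template = SynapticDrive(**entry)
        entry["nu_I"] = calibrate_nu_I(neuron, template, config.get("target_rate_hz", 15.0))
    return StateConfig(label=label, drive=SynapticDrive(**entry), neuron=neuron)


# ---------------------------------------------------------------------------
# spike trains
# ---------------------------------------------------------------------------

_HEADER = "neuron_id\ttime_ms"


def write_spike_trains(path: str | Path, trains: list[SpikeTrain]) -> None:
    """Write trains as two-column TSV with a header; repr-precision times."""
    with open(path, "w") as fh:
        if trains:
            fh.write(_HEADER + f"\t# duration_ms={float(trains[0].duration)!r}\n")
        else:
            fh.write(_HEADER + "\n")
        for i, tr in enumerate(trains):
            for t in tr.times:
                fh.write(f"{i}\t{float(t)!r}\n")


def read_spike_trains(path: str | Path, duration: float | None = None) -> list[SpikeTrain]:
    """Read a spike-train table; non-monotone times raise with the line number."""
    times: dict[int, list[float]] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("neuron_id"):
            raise ValueError(f"{path}: missing header line")
        if duration is None and "duration_ms=" in header:
            duration = float(header.split("duration_ms=")[1].split()[0])
        for ln, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            try:
                sid, st = line.split("\t")
                i, t = int(sid), float(st)
            except ValueError as e:
                raise ValueError(f"{path}:{ln}: malformed row") from e
            bucket = times.setdefault(i, [])
            if bucket and t <= bucket[-1]:
                raise ValueError(f"{path}:{ln}: non-monotone spike time for neuron {i}")
            bucket.append(t)
    if duration is None:
        duration = max((ts[-1] for ts in times.values() if ts), default=0.0)
    n = max(times) + 1 if times else 0
    return [SpikeTrain(np.asarray(times.get(i, []), dtype=float), duration) for i in range(n)]


def write_manifest(run_dir: str | Path, config: dict, seed: int, **extras) -> Path:
    """Record the resolved configuration, seed, version and wall-clock time."""
    from . import __version__

    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": config,
        "seed": int(seed),
        "version": __version__,
        "wall_clock": time.strftime("%Y-%m-%dT%H:%M:%S"),
        **extras,
    }
    path = run_dir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=_jsonify)
    return path


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")
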