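"""Run configuration: YAML parsing, validation, defaults, and manifests.

A run config has sections ``material:``, ``geometry:``, ``pulse:``,
``sweep:`` and ``synth:``; every key is optional and falls back to the
defaults of the corresponding module, unknown keys are itemised errors.
A :class:`RunManifest` written beside each run's outputs records the fully
resolved configuration, package version, seeds, mesh hash and stage timings,
so any result file can be regenerated from its manifest alone.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field as dfield
from pathlib import Path

import yaml

from . import __version__
from .geometry import CellGeometry, make_geometry
from .params import MaterialParams
from .pulses import StrengthDurationCurve

__all__ = ["RunConfig", "RunManifest", "load_config", "ConfigError"]

_SECTIONS = {"material", "geometry", "pulse", "sweep", "synth", "seed"}

_GEOMETRY_KEYS = {"d_long_um", "aspect_ratio", "box_edge_um", "resolution_um"}
_PULSE_KEYS = {"duration_s", "orientation", "curve", "scale_factor",
               "field_V_per_cm", "table_csv"}
_SWEEP_KEYS = {"durations_s", "orientations"}
_SYNTH_KEYS = {"n_cells", "noise_sd", "n_experiments", "duration_s",
               "field_V_per_cm"}


class ConfigError(ValueError):
    """Invalid run configuration; message itemises every offending field."""


def _check_keys(section: str, given: dict, allowed: set[str], errors: list[str]):
    for k in given:
        if k not in allowed:
            errors.append(f"{section}: unknown key {k!r} (allowed: {sorted(allowed)})")


@dataclass
class RunConfig:
    """Fully resolved configuration for one run."""

    material: MaterialParams
    geometry: CellGeometry
    resolution: float                      # m
    pulse_duration: float | None           # s
    orientation: str
    curve: StrengthDurationCurve
    field_override: float | None           # V/m
    sweep_durations: list[float]
    sweep_orientations: list[str]
    synth: dict
    seed: int
    raw: dict = dfield(default_factory=dict)


def load_config(path_or_mapping) -> RunConfig:
    """Parse and validate a YAML config file (or an already-loaded mapping)."""
    if isinstance(path_or_mapping, (str, Path)):
        with open(path_or_mapping) as fh:
            raw = yaml.safe_load(fh) or {}
    else:
        raw = dict(path_or_mapping or {})

    errors: list[str] = []
    for k in raw:
        if k not in _SECTIONS:
            errors.append(f"unknown top-level section {k!r}")

    mat_sec = raw.get("material") or {}
    try:
        material = MaterialParams.from_config(mat_sec)
    except ValueError as e:
        errors.append(f"material: {e}")
        material = MaterialParams()

    geo = dict(raw.get("geometry") or {})
    _check_keys("geometry", geo, _GEOMETRY_KEYS, errors)
    d_long = float(geo.get("d_long_um", 90.0)) * 1e-6
    aspect = float(geo.get("aspect_ratio", 4.0))
    box = float(geo.get("box_edge_um", 400.0)) * 1e-6
    resolution = float(geo.get("resolution_um", 5.0)) * 1e-6
    try:
        geometry = make_geometry(d_long, aspect, box)
    except ValueError as e:
        errors.append(f"geometry: {e}")
        geometry = make_geometry(90e-6, 4.0, 400e-6)

    pul = dict(raw.get("pulse") or {})
    _check_keys("pulse", pul, _PULSE_KEYS, errors)
    orientation = pul.get("orientation", "parallel")
    if orientation not in ("parallel", "perpendicular"):
        errors.append(f"pulse: orientation must be parallel|perpendicular, "
                      f"got {orientation!r}")
        orientation = "parallel"
    kind = pul.get("curve", "hyperbolic")
    try:
        if kind == "tabulated":
            from .pulses import load_tabulated_curve
            curve = load_tabulated_curve(pul["table_csv"])
        else:
            curve = StrengthDurationCurve(
                kind=kind, scale_factor=float(pul.get("scale_factor", 1.0)))
    except (KeyError, ValueError) as e:
        errors.append(f"pulse: {e}")
        curve = StrengthDurationCurve()
    duration = pul.get("duration_s")
    duration = float(duration) if duration is not None else None
    fo = pul.get("field_V_per_cm")
    field_override = float(fo) * 100.0 if fo is not None else None

    sw = dict(raw.get("sweep") or {})
    _check_keys("sweep", sw, _SWEEP_KEYS, errors)
    sweep_durations = [float(x) for x in sw.get(
        "durations_s", [1e-6, 2e-6, 3e-6, 4e-6, 5e-6, 6e-6, 8e-6, 10e-6])]
    sweep_orients = list(sw.get("orientations", ["parallel", "perpendicular"]))

    syn = dict(raw.get("synth") or {})
    _check_keys("synth", syn, _SYNTH_KEYS, errors)
    synth = {
        "n_cells": int(syn.get("n_cells", 12)),
        "noise_sd": float(syn.get("noise_sd", 3.0)),
        "n_experiments": int(syn.get("n_experiments", 5)),
        "duration_s": float(syn.get("duration_s", 1e-3)),
        "field_V_per_cm": float(syn.get("field_V_per_cm", 200.0)),
    }

    seed = int(raw.get("seed", 0))

    if errors:
        raise ConfigError("invalid configuration:\n  - " + "\n  - ".join(errors))
    return RunConfig(
        material=material, geometry=geometry, resolution=resolution,
        pulse_duration=duration, orientation=orientation, curve=curve,
        field_override=field_override, sweep_durations=sweep_durations,
        sweep_orientations=sweep_orients, synth=synth, seed=seed, raw=raw,
    )


def derive_seed(master: int, stream: str) -> int:
    """Deterministic per-module seed derived from the master seed."""
    import hashlib
    h = hashlib.sha256(f"{master}:{stream}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


@dataclass
class RunManifest:
    """Reproducibility record written beside each run's outputs."""

    command: str
    config: dict
    version: str = __version__
    seed: int = 0
    mesh_hash: str | None = None
    timings_s: dict = dfield(default_factory=dict)
    outputs: list = dfield(default_factory=list)
    started: float = dfield(default_factory=time.time)

    def add_timing(self, stage: str, seconds: float) -> None:
        self.timings_s[stage] = round(seconds, 3)

    def add_output(self, path) -> None:
        self.outputs.append(str(path))

    def write(self, directory) -> Path:
        out = Path(directory) / "manifest.json"
        payload = {
            "command": self.command,
            "version": self.version,
            "seed": self.seed,
            "config": self.config,
            "mesh_hash": self.mesh_hash,
            "timings_s": self.timings_s,
            "outputs": self.outputs,
        }
        out.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
        return out
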