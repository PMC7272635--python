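"""Canonical study protocols: the named sweep configurations and the
derived quantities (crossover durations, extreme orientation ratios, onset
structure) reported by the package.

Each protocol fixes geometry, dose curve and duration grid so the same
computation backs both the command line and the acceptance checks.  All
protocols are deterministic: meshes, pulses and solver settings contain no
random element.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import CellGeometry, make_geometry
from .params import MaterialParams, default_params
from .pulses import StrengthDurationCurve
from .sweep import (CrossoverReport, find_crossover, onset_field,
                    pore_ratio_by_duration, run_condition, sweep_durations)

__all__ = [
    "CrossoverConfig",
    "CROSSOVER_CONFIGS",
    "SWEEP_DURATIONS",
    "NS_DURATIONS",
    "MS_DURATIONS",
    "ONSET_FIELD_GRID",
    "run_crossover_config",
    "extreme_orientation_ratios",
    "onset_structure",
]

#: Duration grid of the microsecond crossover sweeps (s).
SWEEP_DURATIONS = (1e-6, 2e-6, 3e-6, 4e-6, 5e-6, 6e-6, 8e-6, 10e-6)
#: Nanosecond-range durations for the extreme orientation ratios (s).
NS_DURATIONS = (10e-9, 100e-9)
#: Millisecond-range durations for the extreme orientation ratios (s).
MS_DURATIONS = (1e-3, 10e-3)

#: Ascending field grid for onset scans, V/m (100-2500 V/cm, ~x1.5 steps).
ONSET_FIELD_GRID = tuple(
    g * 100.0 for g in (100, 150, 220, 330, 500, 750, 1100, 1700, 2500))


@dataclass(frozen=True)
class CrossoverConfig:
    """One named (geometry, dose-curve) study configuration."""

    name: str
    aspect_ratio: float
    curve_scale: float

    def geometry(self) -> CellGeometry:
        return make_geometry(90e-6, self.aspect_ratio, 400e-6)

    def curve(self) -> StrengthDurationCurve:
        return StrengthDurationCurve(kind="hyperbolic",
                                     scale_factor=self.curve_scale)


#: The three studied configurations: elongated cell with the full
#: hyperbolic dose curve, rounder cell with the half-amplitude curve, and
#: the rounder cell at full (twice-relative) amplitude which shows no
#: crossover.
CROSSOVER_CONFIGS = {
    "A": CrossoverConfig("A", aspect_ratio=4.0, curve_scale=1.0),
    "B": CrossoverConfig("B", aspect_ratio=2.0, curve_scale=0.5),
    "C": CrossoverConfig("C", aspect_ratio=2.0, curve_scale=1.0),
}


def run_crossover_config(
    name: str,
    params: MaterialParams | None = None,
    durations=SWEEP_DURATIONS,
    resolution: float = 5e-6,
) -> tuple[pd.DataFrame, CrossoverReport]:
    """Run one named configuration's duration sweep and locate its crossover.

    Returns the tidy sweep frame and the crossover report.
    """
    cfg = CROSSOVER_CONFIGS[name]
    params = params or default_params()
    frame = sweep_durations(cfg.geometry(), params, cfg.curve(), durations,
                            resolution=resolution)
    rat = pore_ratio_by_duration(frame)
    report = find_crossover(rat.ratio_par_perp, rat.t_pulse_s)
    return frame, report


def extreme_orientation_ratios(
    durations,
    params: MaterialParams | None = None,
    configs=("A", "B"),
    resolution: float = 5e-6,
) -> pd.DataFrame:
    """Orientation pore-count ratios at extreme durations.

    Runs every (config, duration) pair in both orientations with the
    config's dose curve; returns one row per pair with the pore counts and
    the ratios both ways.
    """
    params = params or default_params()
    rows = []
    for cname in configs:
        cfg = CROSSOVER_CONFIGS[cname]
        geom, curve = cfg.geometry(), cfg.curve()
        for t in durations:
            counts = {}
            for orient in ("parallel", "perpendicular"):
                r = run_condition(geom, params, curve, t, orient,
                                  resolution=resolution)
                counts[orient] = r.pore_count
            rows.append({
                "config": cname,
                "t_pulse_s": t,
                "pores_parallel": counts["parallel"],
                "pores_perpendicular": counts["perpendicular"],
                "ratio_perp_par": counts["perpendicular"] / counts["parallel"],
                "ratio_par_perp": counts["parallel"] / counts["perpendicular"],
            })
    return pd.DataFrame(rows)


def onset_structure(
    t_pulse: float = 100e-6,
    aspect_ratios=(2.0, 4.0, 7.0),
    params: MaterialParams | None = None,
    field_grid=ONSET_FIELD_GRID,
    resolution: float = 5e-6,
) -> pd.DataFrame:
    """Onset fields by aspect ratio and orientation at one pulse duration.

    One row per (aspect ratio, orientation) with the onset field in V/m
    (NaN when above the grid) and its grid index.
    """
    params = params or default_params()
    grid = np.asarray(field_grid, dtype=float)
    rows = []
    for ar in aspect_ratios:
        geom = make_geometry(90e-6, ar, 400e-6)
        for orient in ("parallel", "perpendicular"):
            E = onset_field(geom, params, t_pulse, orient, grid,
                            resolution=resolution)
            rows.append({
                "aspect_ratio": ar,
                "orientation": orient,
                "onset_V_per_m": np.nan if E is None else E,
                "grid_index": -1 if E is None else int(np.argmin(np.abs(grid - E))),
            })
    return pd.DataFrame(rows)
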