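"""Duration / orientation / aspect-ratio sweeps and crossover analysis.

For each condition (cell geometry, pulse duration, field orientation) a full
coupled pulse simulation yields the end-of-pulse pore density field; the
whole-cell pore number is the density integrated over the membrane (8x the
modelled octant).  Comparing parallel and perpendicular orientations per
duration gives the pore-number ratio R(t); the duration where R crosses 1 --
located by log-log interpolation -- is the orientation crossover: shorter
pulses porate perpendicular cells more, longer pulses parallel cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .geometry import CellGeometry, Mesh, build_mesh
from .params import MaterialParams
from .pores import MembraneState
from .pulses import PulseSpec, StrengthDurationCurve, equivalent_field
from .solver import CoupledRun, run_coupled_pulse

__all__ = [
    "SimulationResult",
    "CrossoverReport",
    "count_pores",
    "electroporated_fraction",
    "run_condition",
    "sweep_durations",
    "pore_ratio_by_duration",
    "find_crossover",
    "onset_field",
    "ELECTROPORATION_THRESHOLD",
]

#: Pore density above which a membrane patch counts as electroporated, m^-2.
ELECTROPORATION_THRESHOLD = 1e13

#: Default mesh resolution (m) for production sweeps; passes the 2%
#: mesh-doubling convergence criterion on the geometries studied.
DEFAULT_RESOLUTION = 5e-6


def count_pores(state: MembraneState, mesh: Mesh) -> float:
    """Whole-cell pore number: the pore density integrated over the membrane.

    The discrete density field is integrated over dual node patches and
    rescaled from the polyhedral membrane area to the analytic spheroid
    surface area, removing the inscribed-surface area deficit from the
    count (the density field itself is unchanged).
    """
    geom = mesh.geometry
    correction = geom.surface_area / 8.0 / mesh.membrane_area
    return float(8.0 * correction * (mesh.patch_area @ state.N))


def electroporated_fraction(
    state: MembraneState, mesh: Mesh, threshold: float = ELECTROPORATION_THRESHOLD
) -> float:
    """Area fraction of the membrane with pore density above ``threshold``."""
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    above = state.N > threshold
    return float(mesh.patch_area[above].sum() / mesh.patch_area.sum())


@dataclass
class SimulationResult:
    """Summary of one coupled pulse simulation."""

    geometry: CellGeometry
    t_pulse: float
    orientation: str
    E_applied: float          # V/m
    pore_count: float         # whole cell, end of pulse
    resting_count: float      # N0 x meshed membrane area (whole cell)
    area_fraction: float      # electroporated area fraction, end of pulse
    peak_um: float            # max |Um| over facets and time, V
    times: np.ndarray
    pore_count_series: np.ndarray
    final_state: MembraneState
    mesh_hash: str

    @property
    def excess_ratio(self) -> float:
        """End-of-pulse pore count relative to the resting count."""
        return self.pore_count / self.resting_count


_mesh_cache: dict[tuple, Mesh] = {}


def _get_mesh(geom: CellGeometry, resolution: float) -> Mesh:
    key = (geom.d_long, geom.aspect_ratio, geom.box_edge, resolution)
    if key not in _mesh_cache:
        _mesh_cache[key] = build_mesh(geom, resolution)
    return _mesh_cache[key]


def run_condition(
    geom: CellGeometry,
    params: MaterialParams,
    curve: StrengthDurationCurve | None,
    t_pulse: float,
    orientation: str,
    resolution: float = DEFAULT_RESOLUTION,
    E_applied: float | None = None,
    mesh: Mesh | None = None,
    **solver_kwargs,
) -> SimulationResult:
    """Simulate one pulse condition and summarise the end-of-pulse state.

    The field amplitude comes from the strength-duration ``curve`` unless
    ``E_applied`` (V/m) overrides it.  Deterministic for fixed inputs.
    """
    if E_applied is None:
        if curve is None:
            raise ValueError("either curve or E_applied must be given")
        E_applied = equivalent_field(curve, t_pulse)
    if mesh is None:
        mesh = _get_mesh(geom, resolution)
    pulse = PulseSpec(t_pulse=t_pulse, E_applied=E_applied, orientation=orientation)
    run: CoupledRun = run_coupled_pulse(mesh, params, pulse, **solver_kwargs)
    state = run.final_state
    return SimulationResult(
        geometry=geom,
        t_pulse=t_pulse,
        orientation=orientation,
        E_applied=E_applied,
        pore_count=count_pores(state, mesh),
        resting_count=float(mesh.geometry.surface_area * params.N0),
        area_fraction=electroporated_fraction(state, mesh),
        peak_um=float(run.max_um.max()),
        times=run.times,
        pore_count_series=run.pore_count,
        final_state=state,
        mesh_hash=mesh.content_hash(),
    )


def sweep_durations(
    geom: CellGeometry,
    params: MaterialParams,
    curve: StrengthDurationCurve,
    durations: Sequence[float],
    orientations: Sequence[str] = ("parallel", "perpendicular"),
    resolution: float = DEFAULT_RESOLUTION,
    **solver_kwargs,
) -> pd.DataFrame:
    """Run all (duration, orientation) conditions; returns a tidy frame.

    Columns: t_pulse_s, orientation, E_applied_V_per_m, pore_count,
    area_fraction, peak_um_V.
    """
    rows = []
    for t_pulse in durations:
        for orient in orientations:
            r = run_condition(geom, params, curve, t_pulse, orient,
                              resolution=resolution, **solver_kwargs)
            rows.append({
                "t_pulse_s": t_pulse,
                "orientation": orient,
                "E_applied_V_per_m": r.E_applied,
                "pore_count": r.pore_count,
                "area_fraction": r.area_fraction,
                "peak_um_V": r.peak_um,
            })
    return pd.DataFrame(rows)


def pore_ratio_by_duration(frame: pd.DataFrame) -> pd.DataFrame:
    """Parallel/perpendicular pore-count ratio per duration.

    Expects the output of :func:`sweep_durations` with both orientations.
    """
    piv = frame.pivot_table(index="t_pulse_s", columns="orientation",
                            values="pore_count")
    if not {"parallel", "perpendicular"} <= set(piv.columns):
        raise ValueError("frame must contain both orientations")
    out = pd.DataFrame({
        "t_pulse_s": piv.index.values,
        "ratio_par_perp": (piv["parallel"] / piv["perpendicular"]).values,
    })
    return out.sort_values("t_pulse_s").reset_index(drop=True)


@dataclass
class CrossoverReport:
    """Orientation-crossover location from per-duration pore ratios."""

    durations: np.ndarray
    ratios: np.ndarray                 # parallel / perpendicular
    t_crossover: float | None          # s; None when log R never changes sign
    bracket: tuple[float, float] | None

    @property
    def found(self) -> bool:
        return self.t_crossover is not None


def find_crossover(ratios: Sequence[float], durations: Sequence[float]) -> CrossoverReport:
    """Locate where the pore ratio crosses 1 by log-log interpolation.

    Pore counts span orders of magnitude across decade-spaced durations, so
    log R is interpolated linearly in log t between the first bracketing
    pair where its sign changes.  An exact R = 1 grid point is returned as
    the crossover itself; if log R never changes sign there is no crossover.
    """
    durations = np.asarray(durations, dtype=float)
    ratios = np.asarray(ratios, dtype=float)
    if len(durations) < 2:
        raise ValueError("need at least 2 durations")
    if np.any(np.diff(durations) <= 0):
        raise ValueError("durations must be sorted ascending")
    if np.any(ratios <= 0):
        raise ValueError("ratios must be positive")
    logr = np.log(ratios)
    for i in range(len(logr)):
        if logr[i] == 0.0:
            return CrossoverReport(durations, ratios, float(durations[i]),
                                   (float(durations[i]), float(durations[i])))
        if i + 1 < len(logr) and logr[i] * logr[i + 1] < 0:
            lt0, lt1 = np.log(durations[i]), np.log(durations[i + 1])
            f = logr[i] / (logr[i] - logr[i + 1])
            t_x = float(np.exp(lt0 + f * (lt1 - lt0)))
            return CrossoverReport(durations, ratios, t_x,
                                   (float(durations[i]), float(durations[i + 1])))
    return CrossoverReport(durations, ratios, None, None)


#: onset is declared at the first grid field whose end-of-pulse pore count
#: exceeds the resting count by this relative margin (above solver noise)
ONSET_EPSILON = 0.1


def onset_field(
    geom: CellGeometry,
    params: MaterialParams,
    t_pulse: float,
    orientation: str,
    field_grid: Sequence[float],
    resolution: float = DEFAULT_RESOLUTION,
    **solver_kwargs,
) -> float | None:
    """Smallest grid field (V/m) that raises the pore count above rest.

    Scans the ascending ``field_grid`` and returns the first field whose
    end-of-pulse whole-cell pore count exceeds (1 + ONSET_EPSILON) times the
    resting count; None when no grid field does ("above grid").
    """
    field_grid = np.asarray(field_grid, dtype=float)
    if np.any(np.diff(field_grid) <= 0):
        raise ValueError("field_grid must be ascending")
    for E in field_grid:
        r = run_condition(geom, params, None, t_pulse, orientation,
                          resolution=resolution, E_applied=float(E),
                          **solver_kwargs)
        if r.pore_count > (1.0 + ONSET_EPSILON) * r.resting_count:
            return float(E)
    return None
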