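"""Trapezoidal pulse waveforms and strength-duration (iso-effect) dose scaling.

A single monopolar trapezoidal pulse is characterised by its duration, its
nominal field amplitude and its orientation relative to the cell's long axis.
Rise and fall times are fixed at one hundredth of the pulse duration.

To compare different pulse durations at equivalent "dose", the field
amplitude is taken from a strength-duration curve: the hyperbolic form

    E(t) = 520.9 V/cm + 1.43 V/cm / t_ms        (t_ms: duration in ms)

optionally multiplied by a scale factor (0.5 is used to compensate for
larger cell geometry), or a user-supplied tabulated curve interpolated in
log-log space.  All public quantities are SI (V/m, s); V/cm appears only at
explicit I/O boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "PulseSpec",
    "StrengthDurationCurve",
    "waveform",
    "equivalent_field",
    "experimental_field_grid",
    "V_PER_CM",
]

#: Conversion factor: 1 V/cm in V/m.
V_PER_CM = 100.0

#: Rheobase of the hyperbolic strength-duration curve, V/cm.
HYPERBOLIC_RHEOBASE_V_PER_CM = 520.9
#: Hyperbolic coefficient, V/cm per (1/ms).
HYPERBOLIC_COEFF_V_PER_CM_MS = 1.43

Orientation = Literal["parallel", "perpendicular"]


@dataclass(frozen=True)
class PulseSpec:
    """One trapezoidal pulse.

    ``E_applied`` is the nominal applied field (V/m), i.e. the boundary
    voltage divided by the electrode distance (the simulation-box edge).
    ``orientation`` is the field direction relative to the cell's long axis.
    Rise and fall each last ``edge_fraction`` of the duration.
    """

    t_pulse: float
    E_applied: float
    orientation: Orientation = "parallel"
    edge_fraction: float = 0.01

    def __post_init__(self) -> None:
        if self.t_pulse <= 0.0:
            raise ValueError(f"t_pulse must be > 0, got {self.t_pulse}")
        if self.E_applied < 0.0:
            raise ValueError(f"E_applied must be >= 0, got {self.E_applied}")
        if not 0.0 < self.edge_fraction < 0.5:
            raise ValueError("edge_fraction must lie in (0, 0.5)")
        if self.orientation not in ("parallel", "perpendicular"):
            raise ValueError(f"unknown orientation {self.orientation!r}")

    @property
    def t_rise(self) -> float:
        return self.edge_fraction * self.t_pulse

    def breakpoints(self) -> np.ndarray:
        """Times where the waveform slope changes: rise end, fall start/end."""
        tr = self.t_rise
        return np.array([0.0, tr, self.t_pulse - tr, self.t_pulse])


def waveform(pulse: PulseSpec, t: float | np.ndarray) -> np.ndarray:
    """Instantaneous amplitude as a fraction of ``E_applied`` at time ``t``.

    Piecewise linear: 0 -> 1 over the rise, 1 on the plateau, 1 -> 0 over
    the fall, 0 after the pulse.
    """
    t = np.asarray(t, dtype=float)
    tr = pulse.t_rise
    tp = pulse.t_pulse
    up = np.clip(t / tr, 0.0, 1.0)
    down = np.clip((tp - t) / tr, 0.0, 1.0)
    return np.where(t >= tp, 0.0, np.minimum(up, down))


@dataclass(frozen=True)
class StrengthDurationCurve:
    """Iso-effect field amplitude as a function of pulse duration.

    kind:
        ``hyperbolic`` -- rheobase + coefficient / t_ms;
        ``scaled_hyperbolic`` -- the same multiplied by ``scale_factor``;
        ``tabulated`` -- log-log interpolation of user (duration_s, field_V_per_cm)
        pairs, no extrapolation.
    """

    kind: Literal["hyperbolic", "scaled_hyperbolic", "tabulated"] = "hyperbolic"
    rheobase_V_per_cm: float = HYPERBOLIC_RHEOBASE_V_PER_CM
    coeff_V_per_cm_ms: float = HYPERBOLIC_COEFF_V_PER_CM_MS
    scale_factor: float = 1.0
    table: tuple[tuple[float, float], ...] | None = None

    def __post_init__(self) -> None:
        if self.kind == "scaled_hyperbolic" and self.scale_factor == 1.0:
            object.__setattr__(self, "scale_factor", 0.5)
        if self.kind == "tabulated":
            if not self.table or len(self.table) < 2:
                raise ValueError("tabulated curve needs >= 2 (duration, field) pairs")
            d = np.array([p[0] for p in self.table])
            if np.any(np.diff(d) <= 0):
                raise ValueError("tabulated durations must be strictly increasing")
        if self.scale_factor <= 0:
            raise ValueError("scale_factor must be > 0")


def equivalent_field(curve: StrengthDurationCurve, t_pulse: float) -> float:
    """Iso-effect field amplitude in V/m for a pulse of duration ``t_pulse`` (s)."""
    if t_pulse <= 0.0:
        raise ValueError(f"t_pulse must be > 0, got {t_pulse}")
    if curve.kind in ("hyperbolic", "scaled_hyperbolic"):
        t_ms = t_pulse * 1e3
        e_vcm = curve.rheobase_V_per_cm + curve.coeff_V_per_cm_ms / t_ms
        return e_vcm * curve.scale_factor * V_PER_CM
    # tabulated: log-log interpolation, no extrapolation
    dur = np.array([p[0] for p in curve.table])
    fld = np.array([p[1] for p in curve.table])
    if not dur[0] <= t_pulse <= dur[-1]:
        raise ValueError(
            f"duration {t_pulse} s outside tabulated range [{dur[0]}, {dur[-1]}] s"
        )
    e_vcm = float(np.exp(np.interp(np.log(t_pulse), np.log(dur), np.log(fld))))
    return e_vcm * curve.scale_factor * V_PER_CM


def load_tabulated_curve(path) -> StrengthDurationCurve:
    """Read a two-column CSV (duration_s, field_V_per_cm) into a curve."""
    arr = np.loadtxt(path, delimiter=",", comments="#")
    arr = np.atleast_2d(arr)
    pairs = tuple((float(d), float(e)) for d, e in arr)
    return StrengthDurationCurve(kind="tabulated", table=pairs)


#: Field strengths applied in the wet-lab experiments, per pulse duration.
#: Keys are durations in seconds, values are fields in V/cm.
_EXPERIMENTAL_GRID_V_PER_CM: dict[float, tuple[float, ...]] = {
    100e-9: (20e3, 26.6e3, 40e3, 46.6e3),
    1e-6: (1000.0, 1400.0, 1800.0, 2200.0, 2500.0),
    10e-6: (400.0, 600.0, 800.0, 1000.0, 1200.0, 1400.0),
    100e-6: (200.0, 300.0, 400.0, 500.0),
    1e-3: (125.0, 200.0, 300.0, 400.0),
    10e-3: (50.0, 75.0, 100.0, 125.0, 150.0, 175.0),
}


def experimental_field_grid(units: str = "V/cm") -> dict[float, tuple[float, ...]]:
    """The experimental pulse-duration -> field-strength grid.

    Returns a mapping from duration (s) to the tuple of applied field
    strengths, in ``V/cm`` (as printed in the protocol) or ``V/m``.
    """
    if units == "V/cm":
        return {k: v for k, v in _EXPERIMENTAL_GRID_V_PER_CM.items()}
    if units == "V/m":
        return {
            k: tuple(x * V_PER_CM for x in v)
            for k, v in _EXPERIMENTAL_GRID_V_PER_CM.items()
        }
    raise ValueError(f"unknown units {units!r}; use 'V/cm' or 'V/m'")
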