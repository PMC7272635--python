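"""Asymptotic pore-density dynamics and the pore-dependent membrane conductivity.

Per membrane patch, the areal pore density N obeys the asymptotic pore
equation

    dN/dt = alpha * exp((Um/Vep)^2) * (1 - N/N0 * exp(-q (Um/Vep)^2))

driven by the local transmembrane voltage Um.  At fixed Um this is a linear
ODE in N: writing x = (Um/Vep)^2,

    dN/dt = a - b N,   a = alpha e^x,   b = (alpha/N0) e^{(1-q) x},

with equilibrium N_eq = a/b = N0 e^{q x} and relaxation rate b, so the step
update is done with the exact exponential integrator (unconditionally
stable, strictly positivity-preserving).

Pores contribute to the membrane conductivity linearly:

    sigma_m = sigma_m0 + N * 2 pi r_p^2 sigma_p d_m / (pi r_p + 2 d_m).

Pore radius is fixed: only the density evolves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import MaterialParams

__all__ = [
    "MembraneState",
    "pore_rate",
    "equilibrium_density",
    "membrane_conductivity",
    "advance_pores",
]

# (Um/Vep)^2 is clamped at this value in all exponentials.  Physical
# trajectories self-limit near Um ~ 1.5 V (x ~ 34) because pore conductance
# collapses the voltage, so the clamp only guards transient overshoot in
# nanosecond rise phases and keeps every exponential finite in float64.
EXPONENT_CLAMP = 400.0
# q*x is additionally capped so N_eq itself stays finite.
_QX_CLAMP = 600.0
# hard ceiling on the pore density used in the step update: far above any
# physically reachable quench density (~1e15 m^-2) yet low enough that the
# resulting membrane conductivity stays well-conditioned during transient
# voltage overshoot before the conductance quench
N_CAP = 1e19


def _x(Um, params: MaterialParams):
    x = (np.asarray(Um, dtype=float) / params.V_ep) ** 2
    return np.minimum(x, EXPONENT_CLAMP)


@dataclass
class MembraneState:
    """Per-facet membrane state: pore density, conductivity, voltage, time."""

    N: np.ndarray          # pore density, m^-2
    sigma_m: np.ndarray    # membrane conductivity, S/m
    Um: np.ndarray         # transmembrane voltage (intra minus extra), V
    t: float               # time, s

    @classmethod
    def resting(cls, n_facets: int, params: MaterialParams) -> "MembraneState":
        N = np.full(n_facets, params.N0)
        return cls(
            N=N,
            sigma_m=membrane_conductivity(N, params),
            Um=np.zeros(n_facets),
            t=0.0,
        )

    def copy(self) -> "MembraneState":
        return MembraneState(self.N.copy(), self.sigma_m.copy(), self.Um.copy(), self.t)


def pore_rate(N, Um, params: MaterialParams):
    """dN/dt of the asymptotic pore equation, m^-2 s^-1 (vectorized)."""
    x = _x(Um, params)
    return params.alpha * np.exp(x) * (1.0 - np.asarray(N) / params.N0 * np.exp(-params.q * x))


def equilibrium_density(Um, params: MaterialParams):
    """Stationary pore density N_eq(Um) = N0 exp(q (Um/Vep)^2), m^-2."""
    qx = np.minimum(params.q * _x(Um, params), _QX_CLAMP)
    return params.N0 * np.exp(qx)


def membrane_conductivity(N, params: MaterialParams):
    """Membrane conductivity for pore density N, S/m (linear in N)."""
    per_pore = (
        2.0 * np.pi * params.r_p**2 * params.sigma_p * params.d_m
        / (np.pi * params.r_p + 2.0 * params.d_m)
    )
    return params.sigma_m0 + np.asarray(N, dtype=float) * per_pore


def advance_pores(
    state: MembraneState,
    Um_next: np.ndarray,
    dt: float,
    params: MaterialParams,
) -> MembraneState:
    """Advance the pore density by ``dt`` with Um frozen at ``Um_next``.

    Exact solution of the (linear in N) pore equation over the step:

        N(t+dt) = N_eq + (N - N_eq) * exp(-b dt),

    b = (alpha/N0) exp((1-q)(Um/Vep)^2).  Returns a new state with
    ``sigma_m`` recomputed; composition over sub-steps at fixed Um is exact
    to round-off.
    """
    if dt <= 0.0:
        raise ValueError(f"dt must be > 0, got {dt}")
    Um_next = np.asarray(Um_next, dtype=float)
    x = _x(Um_next, params)
    b = params.alpha / params.N0 * np.exp((1.0 - params.q) * x)
    n_eq = equilibrium_density(Um_next, params)
    bdt = np.minimum(b * dt, 700.0)
    decay = np.exp(-bdt)
    # convex-combination form: both terms are non-negative, so N stays
    # strictly positive with no cancellation even when n_eq is astronomical;
    # note n_eq * -expm1(-b dt) ~ alpha exp(x) dt for small b dt (the exact
    # creation flux), so the ceiling must apply to the result, never to n_eq
    n_new = np.minimum(n_eq * (-np.expm1(-bdt)) + state.N * decay, N_CAP)
    return MembraneState(
        N=n_new,
        sigma_m=membrane_conductivity(n_new, params),
        Um=Um_next.copy(),
        t=state.t + dt,
    )
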