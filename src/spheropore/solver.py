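"""Transient quasi-static field solver with a contact-impedance membrane.

The electric potential V satisfies charge conservation in both conductive,
polarisable volumes,

    div( (sigma + eps0*eps_r d/dt) grad V ) = 0,

discretised with P1 tetrahedra and backward Euler.  The membrane is not
resolved in the volume: the intracellular and extracellular sides carry
duplicated surface nodes and are coupled by the thin-layer (contact
impedance) condition

    n . J_1 = (1/d_m) (sigma_m + eps0*eps_m d/dt) (V_1 - V_2),
    n . J_2 = (1/d_m) (sigma_m + eps0*eps_m d/dt) (V_2 - V_1),

with per-facet membrane conductivity sigma_m (which the pore dynamics make
voltage-history dependent).  Boundary conditions exploit the octant
antisymmetry: the outer box face normal to the field is driven at +V_app/2,
the coordinate plane normal to the field is held at 0 V, and all remaining
faces are insulating (natural).

Each backward-Euler step solves one sparse SPD system; the membrane
capacitive term is treated implicitly, so the stiff membrane-charging
dynamics (~ microseconds) are unconditionally stable across pulse durations
from nanoseconds to milliseconds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .geometry import Mesh
from .params import MaterialParams
from .pores import MembraneState, advance_pores, membrane_conductivity
from .pulses import PulseSpec, waveform

__all__ = [
    "FieldState",
    "TransientFieldSolver",
    "solve_transient",
    "transmembrane_profile",
    "charging_time_constant",
    "run_coupled_pulse",
    "CoupledRun",
]

_AXIS_OF_ORIENTATION = {"parallel": 0, "perpendicular": 1}


def charging_time_constant(radius: float, params: MaterialParams) -> float:
    """First-order membrane charging time of a sphere of given radius.

    tau = R * C_m * (sigma_i + 2 sigma_e) / (2 sigma_i sigma_e), the classic
    RC time of passive membrane charging in a uniform field; used here as a
    time-scale estimate for step-size initialisation and as a test oracle.
    """
    return (
        radius * params.c_m * (params.sigma_i + 2.0 * params.sigma_e)
        / (2.0 * params.sigma_i * params.sigma_e)
    )


@dataclass
class FieldState:
    """Solution snapshot: node potentials and per-facet transmembrane voltage."""

    V: np.ndarray
    Um: np.ndarray
    t: float


class TransientFieldSolver:
    """Backward-Euler field stepper on a fixed mesh, field axis and parameters.

    Assembles the bulk conduction and polarisation stiffness matrices once;
    per step only the membrane coupling weights and the 1/dt scaling change.
    """

    def __init__(self, mesh: Mesh, params: MaterialParams, orientation: str = "parallel"):
        if orientation not in _AXIS_OF_ORIENTATION:
            raise ValueError(f"unknown orientation {orientation!r}")
        self.mesh = mesh
        self.params = params
        self.orientation = orientation
        self.axis = _AXIS_OF_ORIENTATION[orientation]
        self._assemble_bulk()
        self._assemble_membrane_structure()
        self._build_reduction()

    # -- assembly ------------------------------------------------------------

    def _assemble_bulk(self) -> None:
        mesh, p = self.mesh, self.params
        pts = mesh.vertices[mesh.tets]                       # (nt, 4, 3)
        M = pts[:, 1:] - pts[:, :1]                          # (nt, 3, 3)
        det = np.linalg.det(M)
        vol = np.abs(det) / 6.0
        # rows of M are edge vectors p_i - p_0, so grad(lambda_i) are the
        # columns of M^-1
        Minv_T = np.linalg.inv(M).transpose(0, 2, 1)
        G = np.empty((len(M), 4, 3))
        G[:, 1:, :] = Minv_T
        G[:, 0, :] = -Minv_T.sum(axis=1)
        Ke = vol[:, None, None] * (G @ G.transpose(0, 2, 1))  # (nt, 4, 4)

        sig = np.where(mesh.tet_region == 0, p.sigma_i, p.sigma_e)
        eps = p.eps0 * np.where(mesh.tet_region == 0, p.eps_i, p.eps_e)
        rows = np.broadcast_to(mesh.tets[:, :, None], Ke.shape).ravel()
        cols = np.broadcast_to(mesh.tets[:, None, :], Ke.shape).ravel()
        self._bulk_rows = rows
        self._bulk_cols = cols
        self._bulk_data_sigma = (Ke * sig[:, None, None]).ravel()
        self._bulk_data_eps = (Ke * eps[:, None, None]).ravel()
        n = mesh.n_vertices
        self.K_eps = sp.csr_matrix(
            (self._bulk_data_eps, (rows, cols)), shape=(n, n))
        self.K_sigma = sp.csr_matrix(
            (self._bulk_data_sigma, (rows, cols)), shape=(n, n))

    def _assemble_membrane_structure(self) -> None:
        mesh = self.mesh
        n = mesh.n_vertices
        pairs = mesh.mem_pairs
        n_pairs = len(pairs)
        pair_of_in = np.full(n, -1, dtype=np.int64)
        pair_of_in[pairs[:, 0]] = np.arange(n_pairs)
        # lumped facet-to-pair area operator: w_pair = sum_f (area_f / 3) c_f
        tri_pairs = pair_of_in[mesh.mem_tris_in]             # (nf, 3)
        rows = tri_pairs.ravel()
        cols = np.repeat(np.arange(mesh.n_facets), 3)
        data = np.repeat(mesh.facet_area / 3.0, 3)
        self._F = sp.csr_matrix((data, (rows, cols)), shape=(n_pairs, mesh.n_facets))
        self.pair_area = np.asarray(self._F.sum(axis=1)).ravel()
        ip, op = pairs[:, 0], pairs[:, 1]
        self._mem_rows = np.concatenate([ip, ip, op, op])
        self._mem_cols = np.concatenate([ip, op, ip, op])
        self._pairs_in = ip
        self._pairs_out = op

    def _build_reduction(self) -> None:
        mesh = self.mesh
        n = mesh.n_vertices
        self.driven = mesh.node_mask_box_face(self.axis)
        self.ground = mesh.node_mask_plane(self.axis)
        fixed = self.driven | self.ground
        self.free = ~fixed
        red = np.full(n, -1, dtype=np.int64)
        red[self.free] = np.arange(self.free.sum())
        self._n_free = int(self.free.sum())
        # bulk entries
        br, bc = self._bulk_rows, self._bulk_cols
        keep = (red[br] >= 0) & (red[bc] >= 0)
        self._bulk_keep = keep
        self._bulk_rr = red[br[keep]]
        self._bulk_cc = red[bc[keep]]
        # driven-column contributions (Dirichlet elimination); ground cols are 0
        dmask = (red[br] >= 0) & self.driven[bc]
        self._b_sigma = np.zeros(self._n_free)
        self._b_eps = np.zeros(self._n_free)
        np.add.at(self._b_sigma, red[br[dmask]], self._bulk_data_sigma[dmask])
        np.add.at(self._b_eps, red[br[dmask]], self._bulk_data_eps[dmask])
        # membrane entries (membrane nodes are never on the driven face)
        mr, mc = self._mem_rows, self._mem_cols
        keep_m = (red[mr] >= 0) & (red[mc] >= 0)
        self._mem_keep = keep_m
        self._mem_rr = red[mr[keep_m]]
        self._mem_cc = red[mc[keep_m]]

    # -- stepping ------------------------------------------------------------

    def drive_voltage(self, pulse: PulseSpec, t: float) -> float:
        """Dirichlet value on the driven face: E * box_edge/2 * waveform(t)."""
        return float(
            pulse.E_applied * self.mesh.geometry.box_edge / 2.0
            * waveform(pulse, t)
        )

    def pair_jump(self, V: np.ndarray) -> np.ndarray:
        """Per-pair transmembrane voltage V_in - V_out."""
        return V[self._pairs_in] - V[self._pairs_out]

    def facet_um(self, V: np.ndarray) -> np.ndarray:
        """Per-facet transmembrane voltage (vertex average of the node jump)."""
        return (
            V[self.mesh.mem_tris_in].mean(axis=1)
            - V[self.mesh.mem_tris_out].mean(axis=1)
        )

    def _pair_sigma(self, sigma_m) -> np.ndarray:
        """Membrane conductivity per node pair from a scalar, per-pair or
        per-facet specification (facet values are area-averaged to pairs)."""
        sig = np.asarray(sigma_m, dtype=float)
        if sig.ndim == 0:
            return np.full(len(self.pair_area), float(sig))
        if len(sig) == len(self.pair_area):
            return sig
        if len(sig) == self.mesh.n_facets:
            return (self._F @ sig) / self.pair_area
        raise ValueError("sigma_m must be scalar, per-pair or per-facet")

    def step(
        self,
        V_old: np.ndarray,
        sigma_m: np.ndarray | float,
        dt: float,
        v_drive: float,
    ) -> np.ndarray:
        """One backward-Euler step; returns the new node potential vector."""
        p = self.params
        c_cap = p.c_m / dt                               # S/m^2, capacitive
        w_cond = self.pair_area * self._pair_sigma(sigma_m) / p.d_m
        w_cap = self.pair_area * c_cap                   # per-pair capacitive
        w_tot = w_cond + w_cap
        mem_data = np.concatenate([w_tot, -w_tot, -w_tot, w_tot])

        data = np.concatenate([
            self._bulk_data_sigma[self._bulk_keep]
            + self._bulk_data_eps[self._bulk_keep] / dt,
            mem_data[self._mem_keep],
        ])
        rows = np.concatenate([self._bulk_rr, self._mem_rr])
        cols = np.concatenate([self._bulk_cc, self._mem_cc])
        A = sp.csr_matrix((data, (rows, cols)),
                          shape=(self._n_free, self._n_free))

        rhs_full = self.K_eps @ V_old / dt
        jump_old = self.pair_jump(V_old)
        np.add.at(rhs_full, self._pairs_in, w_cap * jump_old)
        np.add.at(rhs_full, self._pairs_out, -w_cap * jump_old)
        rhs = rhs_full[self.free] - v_drive * (self._b_sigma + self._b_eps / dt)

        lu = spla.splu(A.tocsc())
        x = lu.solve(rhs)
        if not np.all(np.isfinite(x)):
            raise RuntimeError(
                "linear solve produced non-finite values "
                f"(dt={dt:g}, max|rhs|={np.abs(rhs).max():g})"
            )
        V = np.empty(self.mesh.n_vertices)
        V[self.free] = x
        V[self.driven] = v_drive
        V[self.ground] = 0.0
        return V

    # -- diagnostics ---------------------------------------------------------

    def boundary_currents(self, V_new: np.ndarray, V_old: np.ndarray,
                          sigma_m: np.ndarray | float, dt: float) -> dict:
        """Net currents (A) through the driven face and the ground midplane.

        Computed as Dirichlet reaction sums of the discrete operator; by
        charge conservation the two must balance to solver tolerance.
        """
        p = self.params
        w_cond = self.pair_area * self._pair_sigma(sigma_m) / p.d_m
        w_cap = self.pair_area * p.c_m / dt
        jump_new = self.pair_jump(V_new)
        jump_old = self.pair_jump(V_old)
        mem_flux = w_cond * jump_new + w_cap * (jump_new - jump_old)
        r = self.K_sigma @ V_new + self.K_eps @ (V_new - V_old) / dt
        np.add.at(r, self._pairs_in, mem_flux)
        np.add.at(r, self._pairs_out, -mem_flux)
        return {
            "driven": float(r[self.driven].sum()),
            "ground": float(r[self.ground].sum()),
            "membrane": float(mem_flux.sum()),
        }


def solve_transient(
    mesh: Mesh,
    params: MaterialParams,
    pulse: PulseSpec,
    sigma_m,
    t_grid: np.ndarray,
    max_wave_step: float = 0.25,
) -> list[FieldState]:
    """Linear-membrane transient solve on a prescribed time grid.

    ``sigma_m`` is a per-facet membrane conductivity provider: a scalar, an
    array, or a callable of time returning either.  Grid intervals over
    which the waveform changes by more than ``max_wave_step`` of full scale
    are subdivided internally (with a warning) so edges stay resolved;
    returned states are at the requested grid points only.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid[0] != 0.0 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be strictly increasing and start at 0")

    def sig_at(t: float):
        s = sigma_m(t) if callable(sigma_m) else sigma_m
        s = np.asarray(s, dtype=float)
        if np.any(s <= 0):
            raise ValueError("sigma_m provider returned non-positive values")
        return s

    solver = TransientFieldSolver(mesh, params, pulse.orientation)
    V = np.zeros(mesh.n_vertices)
    out = [FieldState(V=V.copy(), Um=solver.pair_jump(V), t=0.0)]
    for t0, t1 in zip(t_grid[:-1], t_grid[1:]):
        dwave = abs(float(waveform(pulse, t1)) - float(waveform(pulse, t0)))
        n_sub = max(1, int(np.ceil(dwave / max_wave_step)))
        if n_sub > 1:
            warnings.warn(
                f"time step [{t0:g}, {t1:g}] spans a waveform change of "
                f"{dwave:.2f}; subdividing into {n_sub} sub-steps",
                stacklevel=2,
            )
        ts = np.linspace(t0, t1, n_sub + 1)
        for ta, tb in zip(ts[:-1], ts[1:]):
            V = solver.step(V, sig_at(tb), tb - ta,
                            solver.drive_voltage(pulse, tb))
        out.append(FieldState(V=V.copy(), Um=solver.pair_jump(V), t=float(t1)))
    return out


def transmembrane_profile(state: FieldState, mesh: Mesh,
                          axis: int = 0) -> np.ndarray:
    """(polar angle from the field axis, Um) per membrane patch, sorted by
    angle.  Returns an (n_patches, 2) array; angle in radians.
    """
    ang = mesh.patch_polar_angle(axis)
    order = np.argsort(ang, kind="stable")
    return np.column_stack([ang[order], state.Um[order]])


# ---------------------------------------------------------------------------
# coupled field / pore-dynamics pulse simulation
# ---------------------------------------------------------------------------

@dataclass
class CoupledRun:
    """Trajectory of one coupled pulse simulation."""

    times: np.ndarray            # accepted step times, s
    pore_count: np.ndarray       # whole-cell pore number at each time
    max_um: np.ndarray           # max |Um| over facets at each time, V
    final_state: MembraneState   # membrane state at end of pulse
    final_V: np.ndarray          # node potentials at end of pulse
    n_steps: int
    n_solves: int


def run_coupled_pulse(
    mesh: Mesh,
    params: MaterialParams,
    pulse: PulseSpec,
    um_iter_tol: float = 0.005,
    dum_target: float = 0.1,
    dlogn_target: float = 0.5,
    max_inner: int = 30,
) -> CoupledRun:
    """Simulate one trapezoidal pulse with field <-> pore coupling.

    Staggered scheme per time step: solve the field implicitly with the
    current membrane conductivity, advance the pore density with the new
    transmembrane voltage via the exact exponential integrator, recompute
    sigma_m, and repeat (log-damped) until the per-facet Um changes by less
    than ``um_iter_tol`` between inner iterates.  Step size adapts to keep
    the per-step change of Um below ``dum_target`` (relative to the current
    voltage scale) and of log10 N below ``dlogn_target``; steps are clamped
    to waveform breakpoints so pulse edges are always resolved.
    """
    solver = TransientFieldSolver(mesh, params, pulse.orientation)
    state = MembraneState.resting(len(mesh.mem_pairs), params)
    V = np.zeros(mesh.n_vertices)

    tau = charging_time_constant(mesh.geometry.a, params)
    t_end = pulse.t_pulse
    breakpoints = [b for b in pulse.breakpoints() if 0.0 < b <= t_end]
    dt = min(pulse.t_rise / 5.0, tau / 20.0, t_end / 20.0)
    dt_min = max(t_end * 1e-9, dt * 1e-6)
    dt_max = t_end / 10.0

    area8 = 8.0 * mesh.patch_area
    times = [0.0]
    counts = [float(area8 @ state.N)]
    max_um = [0.0]
    t = 0.0
    n_steps = 0
    n_solves = 0

    while t < t_end * (1.0 - 1e-12):
        dt = min(dt, dt_max)
        t_next = min(t + dt, t_end)
        for b in breakpoints:
            if t < b - 1e-15 * t_end:
                t_next = min(t_next, b)
                break
        dt_eff = t_next - t
        v_drive = solver.drive_voltage(pulse, t_next)

        # inner staggered iteration at fixed dt
        sigma_iter = state.sigma_m
        um_prev = None
        converged = False
        for it in range(max_inner):
            V_new = solver.step(V, sigma_iter, dt_eff, v_drive)
            n_solves += 1
            um = solver.pair_jump(V_new)
            mem_new = advance_pores(state, um, dt_eff, params)
            if um_prev is not None:
                scale = max(float(np.abs(um_prev).max()), 0.05)
                if float(np.abs(um - um_prev).max()) / scale < um_iter_tol:
                    converged = True
                    break
            um_prev = um
            # geometric damping keeps the sigma <-> Um feedback stable when
            # pore creation is fast
            sigma_iter = np.sqrt(sigma_iter * mem_new.sigma_m)

        dum = float(np.abs(um - state.Um).max()) / max(
            float(np.abs(state.Um).max()), 0.05)
        dlogn = float(np.abs(np.log10(mem_new.N / state.N)).max())
        ok = converged and dum <= 2.0 * dum_target and dlogn <= 2.0 * dlogn_target
        if not ok and dt_eff > dt_min:
            dt = dt_eff / 2.0
            continue

        # accept
        V = V_new
        state = mem_new
        t = t_next
        n_steps += 1
        times.append(t)
        counts.append(float(area8 @ state.N))
        max_um.append(float(np.abs(um).max()))
        if dum < 0.5 * dum_target and dlogn < 0.5 * dlogn_target:
            dt = dt_eff * 1.6
        else:
            dt = dt_eff

    return CoupledRun(
        times=np.array(times),
        pore_count=np.array(counts),
        max_um=np.array(max_um),
        final_state=state,
        final_V=V,
        n_steps=n_steps,
        n_solves=n_solves,
    )
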