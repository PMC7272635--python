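import warnings

import numpy as np
import pytest

from spheropore.geometry import build_mesh, make_geometry
from spheropore.params import default_params
from spheropore.pulses import PulseSpec
from spheropore.solver import (TransientFieldSolver, charging_time_constant,
                               run_coupled_pulse, solve_transient,
                               transmembrane_profile)

P = default_params()


def _plateau_state(mesh, params, E, orientation="parallel", n_tau=8, steps=120):
    tau = charging_time_constant(mesh.geometry.a, params)
    pulse = PulseSpec(t_pulse=n_tau * tau, E_applied=E,
                      orientation=orientation, edge_fraction=0.001)
    t_grid = np.concatenate([[0], np.linspace(n_tau * tau / steps,
                                              n_tau * tau, steps)])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        states = solve_transient(mesh, params, pulse, params.sigma_m0, t_grid)
    return states[-3]  # still on the plateau, before the fall edge


class TestUniformConductor:
    def test_linear_potential_when_membrane_transparent(self):
        """Equal conductivities and a transparent membrane give V = E*x."""
        params = P.with_(sigma_i=1.0, sigma_e=1.0)
        mesh = build_mesh(make_geometry(90e-6, 1.0, 400e-6), 8e-6)
        E = 1e4
        pulse = PulseSpec(t_pulse=1e-3, E_applied=E, edge_fraction=0.001)
        t_grid = np.array([0.0, 2e-4, 5e-4])
        states = solve_transient(mesh, params, pulse, 1e3, t_grid)
        V = states[-1].V
        expected = E * mesh.vertices[:, 0]
        err = np.abs(V - expected)
        drive = E * mesh.geometry.box_edge / 2
        # the outer shell chamfers the box edges, locally distorting the
        # natural boundary there; hold the tight bound away from the edges
        interior = np.max(np.abs(mesh.vertices), axis=1) < 0.8 * (
            mesh.geometry.box_edge / 2)
        assert err[interior].max() < 0.02 * drive
        assert err.max() < 0.06 * drive


class TestMembraneChargingOracles:
    def test_steady_state_is_schwan_cosine(self, sphere_mesh_coarse):
        """|Um| -> 1.5 E R cos(theta) on an insulating-membrane sphere."""
        E = 1e4
        R = sphere_mesh_coarse.geometry.a
        st = _plateau_state(sphere_mesh_coarse, P, E)
        ang = sphere_mesh_coarse.patch_polar_angle(0)
        expected = 1.5 * E * R * np.cos(ang)
        err = np.abs(np.abs(st.Um) - expected) / (1.5 * E * R)
        assert err.max() < 0.05   # coarse test mesh; 3% bound at default mesh

    def test_profile_maximal_at_pole_and_zero_without_field(
            self, sphere_mesh_coarse):
        E = 1e4
        st = _plateau_state(sphere_mesh_coarse, P, E)
        prof = transmembrane_profile(st, sphere_mesh_coarse, axis=0)
        # sorted by angle: magnitude decreases from pole to equator
        assert abs(prof[0, 1]) == pytest.approx(np.abs(prof[:, 1]).max(),
                                                rel=0.02)
        assert abs(prof[-1, 1]) < 0.05 * abs(prof[0, 1])
        zero = solve_transient(
            sphere_mesh_coarse, P,
            PulseSpec(t_pulse=1e-6, E_applied=0.0), P.sigma_m0,
            np.array([0.0, 5e-7]))[-1]
        np.testing.assert_allclose(zero.Um, 0.0, atol=1e-15)

    def test_linearity_in_applied_voltage(self, sphere_mesh_coarse):
        """With fixed sigma_m the problem is linear: doubling E doubles Um."""
        st1 = _plateau_state(sphere_mesh_coarse, P, 1e4, steps=40)
        st2 = _plateau_state(sphere_mesh_coarse, P, 2e4, steps=40)
        np.testing.assert_allclose(st2.Um, 2 * st1.Um, rtol=1e-9, atol=1e-9)

    def test_current_conservation(self, sphere_mesh_coarse):
        """Driven-face and midplane reaction currents balance each step."""
        mesh = sphere_mesh_coarse
        solver = TransientFieldSolver(mesh, P, "parallel")
        pulse = PulseSpec(t_pulse=1e-5, E_applied=1e4, edge_fraction=0.01)
        V = np.zeros(mesh.n_vertices)
        dt = 2e-7
        for k in range(1, 6):
            V_new = solver.step(V, P.sigma_m0, dt,
                                solver.drive_voltage(pulse, k * dt))
            cur = solver.boundary_currents(V_new, V, P.sigma_m0, dt)
            assert cur["driven"] == pytest.approx(-cur["ground"], rel=1e-6)
            V = V_new

    def test_time_grid_validation(self, sphere_mesh_coarse):
        pulse = PulseSpec(t_pulse=1e-6, E_applied=1e4)
        with pytest.raises(ValueError, match="increasing"):
            solve_transient(sphere_mesh_coarse, P, pulse, P.sigma_m0,
                            np.array([0.0, 2e-7, 1e-7]))
        with pytest.raises(ValueError, match="sigma_m"):
            solve_transient(sphere_mesh_coarse, P, pulse, -1.0,
                            np.array([0.0, 1e-7]))


class TestCoupledPulse:
    def test_sphere_orientation_independence(self, sphere_mesh_coarse):
        """A spherical cell porates identically for both field orientations."""
        pulse_par = PulseSpec(t_pulse=1e-6, E_applied=1.5e5,
                              orientation="parallel")
        pulse_perp = PulseSpec(t_pulse=1e-6, E_applied=1.5e5,
                               orientation="perpendicular")
        r_par = run_coupled_pulse(sphere_mesh_coarse, P, pulse_par)
        r_perp = run_coupled_pulse(sphere_mesh_coarse, P, pulse_perp)
        c_par = 8 * (sphere_mesh_coarse.patch_area @ r_par.final_state.N)
        c_perp = 8 * (sphere_mesh_coarse.patch_area @ r_perp.final_state.N)
        assert c_par == pytest.approx(c_perp, rel=0.05)

    def test_zero_amplitude_stays_at_rest(self, prolate_mesh_coarse):
        pulse = PulseSpec(t_pulse=1e-6, E_applied=0.0)
        run = run_coupled_pulse(prolate_mesh_coarse, P, pulse)
        np.testing.assert_allclose(run.final_state.N, P.N0, rtol=1e-9)
        assert run.max_um.max() == 0.0

    def test_pore_count_monotone_during_plateau(self, prolate_mesh_coarse):
        pulse = PulseSpec(t_pulse=1e-6, E_applied=1.5e5,
                          orientation="perpendicular")
        run = run_coupled_pulse(prolate_mesh_coarse, P, pulse)
        on_plateau = run.times < 0.99 * pulse.t_pulse
        counts = run.pore_count[on_plateau]
        assert np.all(np.diff(counts) >= -1e-9 * counts[:-1])
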