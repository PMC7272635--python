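import numpy as np
import pandas as pd
import pytest

from spheropore.geometry import make_geometry
from spheropore.params import default_params
from spheropore.pores import MembraneState
from spheropore.sweep import (ELECTROPORATION_THRESHOLD, count_pores,
                              electroporated_fraction, find_crossover,
                              onset_field, pore_ratio_by_duration,
                              run_condition)

P = default_params()


class TestCountPores:
    def test_resting_state_gives_n0_times_surface(self, prolate_mesh_coarse):
        """Uniform density N0 integrates to exactly N0 x analytic area:
        the polyhedral-area deficit is removed by the area correction."""
        m = prolate_mesh_coarse
        state = MembraneState.resting(len(m.patch_area), P)
        expected = P.N0 * m.geometry.surface_area
        assert count_pores(state, m) == pytest.approx(expected, rel=1e-12)

    def test_linear_in_density(self, prolate_mesh_coarse):
        m = prolate_mesh_coarse
        s1 = MembraneState.resting(len(m.patch_area), P)
        s2 = s1.copy()
        s2.N = 3.0 * s1.N
        assert count_pores(s2, m) == pytest.approx(3 * count_pores(s1, m))


class TestElectroporatedFraction:
    def test_extremes(self, prolate_mesh_coarse):
        m = prolate_mesh_coarse
        below = MembraneState.resting(len(m.patch_area), P)
        assert electroporated_fraction(below, m) == 0.0
        above = below.copy()
        above.N = np.full_like(below.N, 10 * ELECTROPORATION_THRESHOLD)
        assert electroporated_fraction(above, m) == 1.0

    def test_partial_fraction_is_area_weighted(self, prolate_mesh_coarse):
        m = prolate_mesh_coarse
        state = MembraneState.resting(len(m.patch_area), P)
        hot = np.argsort(m.patch_area)[-5:]
        state.N[hot] = 10 * ELECTROPORATION_THRESHOLD
        expected = m.patch_area[hot].sum() / m.patch_area.sum()
        assert electroporated_fraction(state, m) == pytest.approx(expected)

    def test_invalid_threshold(self, prolate_mesh_coarse):
        state = MembraneState.resting(
            len(prolate_mesh_coarse.patch_area), P)
        with pytest.raises(ValueError):
            electroporated_fraction(state, prolate_mesh_coarse, threshold=0.0)


class TestFindCrossover:
    def test_log_log_interpolation(self):
        """Ratios 0.5 at 1 us and 5 at 10 us cross 1 at 2.0 us exactly
        under log-log interpolation."""
        rep = find_crossover([0.5, 5.0], [1e-6, 10e-6])
        assert rep.found
        assert rep.t_crossover == pytest.approx(2.0e-6, rel=1e-12)
        assert rep.bracket == (1e-6, 10e-6)

    def test_exact_grid_point(self):
        rep = find_crossover([0.5, 1.0, 2.0], [1e-6, 3e-6, 10e-6])
        assert rep.t_crossover == pytest.approx(3e-6)

    def test_no_crossover(self):
        rep = find_crossover([0.4, 0.5, 0.9], [1e-6, 3e-6, 10e-6])
        assert not rep.found
        assert rep.t_crossover is None and rep.bracket is None

    def test_first_bracket_wins(self):
        rep = find_crossover([0.5, 2.0, 0.5, 2.0],
                             [1e-6, 2e-6, 4e-6, 8e-6])
        assert rep.bracket == (1e-6, 2e-6)

    def test_validation(self):
        with pytest.raises(ValueError):
            find_crossover([1.0], [1e-6])
        with pytest.raises(ValueError):
            find_crossover([1.0, 2.0], [2e-6, 1e-6])
        with pytest.raises(ValueError):
            find_crossover([1.0, -2.0], [1e-6, 2e-6])


class TestPoreRatio:
    def test_pivot_and_ratio(self):
        frame = pd.DataFrame([
            {"t_pulse_s": 1e-6, "orientation": "parallel", "pore_count": 10.0},
            {"t_pulse_s": 1e-6, "orientation": "perpendicular", "pore_count": 40.0},
            {"t_pulse_s": 5e-6, "orientation": "parallel", "pore_count": 90.0},
            {"t_pulse_s": 5e-6, "orientation": "perpendicular", "pore_count": 30.0},
        ])
        out = pore_ratio_by_duration(frame)
        np.testing.assert_allclose(out.ratio_par_perp, [0.25, 3.0])

    def test_missing_orientation_rejected(self):
        frame = pd.DataFrame([
            {"t_pulse_s": 1e-6, "orientation": "parallel", "pore_count": 1.0}])
        with pytest.raises(ValueError, match="both orientations"):
            pore_ratio_by_duration(frame)


class TestRunCondition:
    def test_zero_field_stays_at_rest(self, prolate_mesh_coarse):
        r = run_condition(prolate_mesh_coarse.geometry, P, None, 1e-6,
                          "parallel", E_applied=0.0, mesh=prolate_mesh_coarse)
        assert r.pore_count == pytest.approx(r.resting_count, rel=1e-9)
        assert r.excess_ratio == pytest.approx(1.0, rel=1e-9)
        assert r.area_fraction == 0.0
        assert r.peak_um == 0.0

    def test_requires_curve_or_field(self, prolate_mesh_coarse):
        with pytest.raises(ValueError, match="curve or E_applied"):
            run_condition(prolate_mesh_coarse.geometry, P, None, 1e-6,
                          "parallel", mesh=prolate_mesh_coarse)

    def test_strong_pulse_porates(self, prolate_mesh_coarse):
        r = run_condition(prolate_mesh_coarse.geometry, P, None, 1e-6,
                          "parallel", E_applied=1.5e5,
                          mesh=prolate_mesh_coarse)
        assert r.pore_count > 100 * r.resting_count
        assert 0 < r.area_fraction <= 1.0
        assert r.peak_um > 0.5


class TestOnsetField:
    def test_grid_validation(self):
        geom = make_geometry(90e-6, 2.0, 400e-6)
        with pytest.raises(ValueError, match="ascending"):
            onset_field(geom, P, 1e-6, "parallel", [2e4, 1e4])

    def test_onset_bracketing(self, prolate_mesh_coarse):
        """A grid spanning rest to strong poration returns an interior
        field, and no field below it porates."""
        geom = prolate_mesh_coarse.geometry
        grid = [1e3, 3e4, 2e5]
        E = onset_field(geom, P, 1e-6, "parallel", grid,
                        mesh=prolate_mesh_coarse)
        assert E in (3e4, 2e5)
        r_low = run_condition(geom, P, None, 1e-6, "parallel",
                              E_applied=1e3, mesh=prolate_mesh_coarse)
        assert r_low.excess_ratio < 1.1
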