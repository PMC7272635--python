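import numpy as np
import pytest

from spheropore.synthexp import (FRAME_TIMES, PEAK_FRAME, PEAK_TIME,
                                 PULSE_TIME, CellMeasurement,
                                 classify_orientation, compute_ratio_trace,
                                 default_effect_model, generate_scene,
                                 measure_scene, parallel_minus_perpendicular,
                                 _response_shape)


class TestClassification:
    @pytest.mark.parametrize("a,b,angle,expected", [
        (30, 10, 5, "parallel"),
        (30, 10, 20, "parallel"),       # boundary inclusive
        (30, 10, 75, "perpendicular"),
        (30, 10, 70, "perpendicular"),  # boundary inclusive
        (30, 10, 45, "rest"),           # elongated but oblique
        (30, 20, 5, "rest"),            # aligned but not elongated
        (30, 15, 5, "rest"),            # a > 2b is strict
    ])
    def test_examples(self, a, b, angle, expected):
        assert classify_orientation(a, b, angle) == expected

    def test_invalid_axes(self):
        with pytest.raises(ValueError):
            classify_orientation(10, 30, 5)
        with pytest.raises(ValueError):
            classify_orientation(30, 10, 120)


class TestAcquisitionTiming:
    def test_protocol_constants(self):
        assert len(FRAME_TIMES) == 15
        assert np.all(np.diff(FRAME_TIMES) == 5.0)
        assert PEAK_TIME == PULSE_TIME + 8.0
        assert FRAME_TIMES[PEAK_FRAME] == PEAK_TIME

    def test_response_shape(self):
        s = _response_shape(FRAME_TIMES)
        assert s[0] == 0.0 and s[1] == 0.0          # before the pulse
        assert s[PEAK_FRAME] == pytest.approx(1.0)  # unit peak at 15 s
        assert np.all(np.diff(s[PEAK_FRAME:]) < 0)  # decays afterwards


class TestRatioTrace:
    def test_constant_channels(self):
        ch340 = np.full((15, 4, 4), 300.0)
        ch380 = np.full((15, 4, 4), 200.0)
        region = np.ones((4, 4), bool)
        trace = compute_ratio_trace(ch340, ch380, region)
        np.testing.assert_allclose(trace, 150.0)
        trace = compute_ratio_trace(ch340, ch380, region, bg340=100, bg380=100)
        np.testing.assert_allclose(trace, 200.0)

    def test_empty_region_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            compute_ratio_trace(np.ones((15, 2, 2)), np.ones((15, 2, 2)),
                                np.zeros((2, 2), bool))

    def test_nonpositive_380_pixels_excluded_with_warning(self):
        ch340 = np.full((15, 1, 2), 300.0)
        ch380 = np.full((15, 1, 2), 200.0)
        ch380[:, 0, 1] = 0.0
        with pytest.warns(UserWarning, match="non-positive"):
            trace = compute_ratio_trace(ch340, ch380, np.ones((1, 2), bool))
        np.testing.assert_allclose(trace, 150.0)


class TestEffectModel:
    def test_sign_structure(self):
        """Perpendicular dominates at 100 ns, parallel at 1-10 ms."""
        g = {100e-9: 40e3, 1e-3: 400.0, 10e-3: 175.0}
        for dur, fld in g.items():
            par = default_effect_model(dur, fld, "parallel")
            perp = default_effect_model(dur, fld, "perpendicular")
            if dur < 1e-6:
                assert perp > par
            else:
                assert par > perp

    def test_equal_in_microsecond_range(self):
        for dur in (1e-6, 10e-6, 100e-6):
            assert default_effect_model(dur, 100.0, "parallel") == \
                default_effect_model(dur, 100.0, "perpendicular")

    def test_linear_in_field(self):
        a1 = default_effect_model(1e-3, 100.0, "parallel")
        a2 = default_effect_model(1e-3, 200.0, "parallel")
        assert a2 == pytest.approx(2 * a1)


class TestSceneGeneration:
    def test_determinism(self):
        s1 = generate_scene(6, default_effect_model, 3.0, seed=11)
        s2 = generate_scene(6, default_effect_model, 3.0, seed=11)
        s3 = generate_scene(6, default_effect_model, 3.0, seed=12)
        assert s1.content_hash() == s2.content_hash()
        assert s1.content_hash() != s3.content_hash()

    def test_both_classes_always_present(self):
        for seed in range(5):
            s = generate_scene(4, default_effect_model, 3.0, seed=seed)
            classes = {c.orientation_class for c in s.cells}
            assert {"parallel", "perpendicular"} <= classes

    def test_ground_truth_classes_consistent(self):
        s = generate_scene(8, default_effect_model, 0.0, seed=3)
        for c in s.cells:
            assert classify_orientation(c.a, c.b, c.angle_deg) == \
                c.orientation_class

    def test_packing_limit_raises(self):
        with pytest.raises(RuntimeError, match="packing"):
            generate_scene(40, default_effect_model, 0.0, seed=0,
                           image_shape=(96, 96), max_tries=200)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            generate_scene(0, default_effect_model, 1.0, seed=0)
        with pytest.raises(ValueError):
            generate_scene(3, default_effect_model, -1.0, seed=0)


class TestPipeline:
    def test_noiseless_identity(self):
        """Rendered noiseless cells are recovered exactly: count, class,
        shape within discretisation error, peak equal to the amplitude."""
        scene = generate_scene(6, default_effect_model, 0.0, seed=21,
                               cell_sd=0.0, duration=1e-3,
                               field_V_per_cm=400.0)
        meas = measure_scene(scene)
        assert len(meas) == len(scene.cells)
        truth = sorted(scene.cells, key=lambda c: (c.center[1], c.center[0]))

        def key(m):
            return tuple(np.round([m.a, m.b], 1))

        classes_true = sorted(c.orientation_class for c in scene.cells)
        classes_meas = sorted(m.orientation_class for m in meas)
        assert classes_meas == classes_true

        # match measurements to ground truth by shape and check recovery
        for c in scene.cells:
            best = min(meas, key=lambda m: abs(m.a - c.a) + abs(m.b - c.b))
            assert best.a == pytest.approx(c.a, rel=0.08)
            assert best.b == pytest.approx(c.b, rel=0.08)
            assert best.angle_deg == pytest.approx(c.angle_deg, abs=2.5)
            assert best.peak == pytest.approx(c.amplitude, abs=0.05)

    def test_parallel_minus_perpendicular_arithmetic(self):
        def mk(cls, peak):
            tr = np.zeros(15); tr[PEAK_FRAME] = peak
            return CellMeasurement(a=30, b=10, angle_deg=5 if cls == "parallel"
                                   else 85, orientation_class=cls,
                                   trace=tr, peak=peak)
        meas = [mk("parallel", 10.0), mk("parallel", 14.0),
                mk("perpendicular", 3.0)]
        assert parallel_minus_perpendicular(meas) == pytest.approx(9.0)

    def test_empty_class_errors(self):
        tr = np.zeros(15)
        only_par = [CellMeasurement(30, 10, 5, "parallel", tr, 1.0)]
        with pytest.raises(ValueError, match="perpendicular"):
            parallel_minus_perpendicular(only_par)

    def test_sign_recovery_one_condition_each_way(self):
        """Millisecond pulse yields a positive difference, nanosecond a
        negative one, through the full render-measure pipeline."""
        ms = generate_scene(8, default_effect_model, 2.0, seed=5,
                            duration=1e-3, field_V_per_cm=400.0)
        ns = generate_scene(8, default_effect_model, 2.0, seed=5,
                            duration=100e-9, field_V_per_cm=46.6e3)
        assert parallel_minus_perpendicular(measure_scene(ms)) > 0
        assert parallel_minus_perpendicular(measure_scene(ns)) < 0
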