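"""Segment geometry, derivatives, event detection, stride normalization."""

import numpy as np
import pytest

from gaitphase.kinematics import (DegenerateGeometryError, GrfTrace, MarkerSet,
                                  MissingMarkerError, angular_velocity,
                                  detect_events, detect_heel_strikes,
                                  interpolate_marker_gaps,
                                  segment_angle_sagittal, thigh_segment_vector,
                                  time_normalize_stride, torso_segment_vector,
                                  walking_direction)


def markers_at(pelvis_z=1.0, t10=(0.0, 0.0, 1.3), n=1):
    quad = {
        "LASI": (0.1, 0.1, pelvis_z), "RASI": (0.1, -0.1, pelvis_z),
        "LPSI": (-0.1, 0.1, pelvis_z), "RPSI": (-0.1, -0.1, pelvis_z),
        "T10": t10, "GTR": (0.0, 0.0, 0.9), "LFE": (0.0, 0.0, 0.5),
    }
    return MarkerSet({k: np.tile(np.asarray(v, float), (n, 1))
                      for k, v in quad.items()})


class TestSegmentVectors:
    def test_torso_vector_construction(self):
        v = torso_segment_vector(markers_at(), 0)
        assert v == pytest.approx([0.0, 0.0, 0.3])

    def test_translation_invariance(self):
        m = markers_at()
        shifted = MarkerSet({k: v + np.array([1.0, 2.0, 3.0])
                             for k, v in m.trajectories.items()})
        assert torso_segment_vector(shifted, 0) == pytest.approx(
            torso_segment_vector(m, 0))
        assert thigh_segment_vector(shifted, 0) == pytest.approx(
            thigh_segment_vector(m, 0))

    def test_missing_marker_named(self):
        m = markers_at()
        del m.trajectories["T10"]
        with pytest.raises(MissingMarkerError, match="T10"):
            torso_segment_vector(m, 0)

    def test_coincident_markers_degenerate_angle(self):
        v = np.zeros(3)
        with pytest.raises(DegenerateGeometryError):
            segment_angle_sagittal(v)


class TestSagittalAngle:
    def test_vertical_is_zero(self):
        assert segment_angle_sagittal(np.array([0, 0, 1.0])) == pytest.approx(0.0)

    def test_forty_five_forward(self):
        v = np.array([np.sqrt(0.5), 0, np.sqrt(0.5)])
        assert segment_angle_sagittal(v) == pytest.approx(45.0)

    def test_ten_degrees_closed_form(self):
        v = np.array([np.sin(np.radians(10)), 0, np.cos(np.radians(10))])
        assert segment_angle_sagittal(v) == pytest.approx(10.0, abs=1e-9)

    def test_thigh_reference_down(self):
        # a vertical thigh (pointing down) reads 0 with the "down" reference
        assert segment_angle_sagittal(np.array([0, 0, -1.0]),
                                      reference="down") == pytest.approx(0.0)

    def test_yaw_invariance_with_reestimated_forward(self):
        """Rotating the lab about +Z leaves sagittal angles unchanged once
        the walking direction is re-estimated."""
        ang = np.radians(73.0)
        R = np.array([[np.cos(ang), -np.sin(ang), 0],
                      [np.sin(ang), np.cos(ang), 0], [0, 0, 1]])
        n = 10
        m = markers_at(n=n)
        # make the pelvis walk along +x so direction is estimable
        for k in m.trajectories:
            m.trajectories[k] = m.trajectories[k] + np.outer(
                np.linspace(0, 1, n), [1.0, 0, 0])
        rot = MarkerSet({k: v @ R.T for k, v in m.trajectories.items()})
        v0 = torso_segment_vector(m, 3)
        v1 = torso_segment_vector(rot, 3)
        a0 = segment_angle_sagittal(v0, walking_direction(m))
        a1 = segment_angle_sagittal(v1, walking_direction(rot))
        assert a1 == pytest.approx(a0, abs=1e-9)


class TestAngularVelocity:
    def test_constant_zero(self):
        assert np.allclose(angular_velocity(np.full(50, 3.0), 100.0), 0.0)

    def test_linear_ramp(self):
        t = np.arange(100) / 250.0
        assert np.allclose(angular_velocity(2 * t, 250.0), 2.0)

    def test_sinusoid_matches_analytic(self):
        t = np.arange(0, 2, 0.01)
        v = angular_velocity(np.sin(2 * np.pi * t), 100.0)
        expected = 2 * np.pi * np.cos(2 * np.pi * t)
        # interior samples: better than 1% of the derivative amplitude
        err = np.max(np.abs(v[1:-1] - expected[1:-1]))
        assert err < 0.01 * 2 * np.pi

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            angular_velocity(np.array([1.0, 2.0]), 100.0)

    def test_differentiation_inverts_integration(self):
        """angular_velocity after cumulative integration is the identity up
        to a constant (discretization error vanishes as O(h^2), so a fine
        grid meets a 1e-6-of-scale tolerance)."""
        from scipy.integrate import cumulative_trapezoid
        fs = 10_000.0
        t = np.arange(0, 0.3, 1 / fs)
        v = 50 * np.cos(2 * np.pi * 0.8 * t)
        integral = cumulative_trapezoid(v, t, initial=0.0)
        rebuilt = angular_velocity(integral, fs)
        err = np.max(np.abs(rebuilt[1:-1] - v[1:-1]))
        assert err < 1e-6 * np.ptp(v) * 10


class TestEventDetection:
    def test_rectangular_pulse(self):
        fs = 1500.0
        f = np.zeros(int(2 * fs))
        f[int(1.0 * fs):int(1.6 * fs)] = 800.0
        hs = detect_heel_strikes(GrfTrace(f, fs), threshold_n=20.0)
        assert len(hs) == 1
        assert abs(hs[0] - 1.0) <= 1.0 / fs

    def test_all_zero_no_events(self):
        assert detect_heel_strikes(GrfTrace(np.zeros(1000))).size == 0

    def test_debounce_merges_close_pulses(self):
        fs = 1500.0
        f = np.zeros(int(1.0 * fs))
        f[int(0.30 * fs):int(0.33 * fs)] = 800.0
        f[int(0.35 * fs):int(0.40 * fs)] = 800.0     # 0.05 s later
        hs = detect_heel_strikes(GrfTrace(f, fs), 20.0, debounce_s=0.1)
        assert len(hs) == 1

    def test_toe_offs_paired(self):
        fs = 1500.0
        f = np.zeros(int(2 * fs))
        f[int(0.5 * fs):int(1.2 * fs)] = 700.0
        hs, to = detect_events(GrfTrace(f, fs), 20.0)
        assert len(hs) == 1 and len(to) == 1
        assert to[0] > hs[0]

    def test_bad_threshold(self):
        with pytest.raises(ValueError):
            detect_heel_strikes(GrfTrace(np.zeros(10)), threshold_n=0.0)


class TestMarkerGapFilling:
    def test_short_gap_linearly_filled(self):
        m = markers_at(n=50)
        traj = m.trajectories["T10"] + np.linspace(0, 1, 50)[:, None]
        traj[10:15] = np.nan                      # 0.05 s gap at 100 Hz
        m.trajectories["T10"] = traj
        filled = interpolate_marker_gaps(m, max_gap_s=0.1)
        got = filled.trajectories["T10"]
        assert np.all(np.isfinite(got))
        expected = traj[9] + (traj[15] - traj[9]) * (np.arange(10, 15)[:, None] - 9) / 6
        assert np.allclose(got[10:15], expected)

    def test_long_gap_left_as_nan(self):
        m = markers_at(n=50)
        traj = m.trajectories["T10"].copy()
        traj[10:30] = np.nan                      # 0.2 s gap
        m.trajectories["T10"] = traj
        filled = interpolate_marker_gaps(m, max_gap_s=0.1)
        assert np.all(np.isnan(filled.trajectories["T10"][10:30]))
        assert np.all(np.isfinite(filled.trajectories["LASI"]))


class TestTimeNormalize:
    def test_constant(self):
        t = np.arange(0, 5, 0.01)
        out = time_normalize_stride(t, np.full_like(t, 7.0), 1.0, 2.0, 101)
        assert np.allclose(out, 7.0)

    def test_time_itself(self):
        t = np.arange(0, 5, 0.01)
        out = time_normalize_stride(t, t, 2.0, 3.0, 101)
        assert np.allclose(out, np.arange(2.0, 3.0001, 0.01), atol=1e-9)

    def test_duration_invariance_of_per_stride_sinusoid(self):
        """A 1-per-stride sinusoid normalizes identically whatever the
        stride duration."""
        t = np.arange(0, 10, 0.01)
        for d0, d1 in [(1.0, 1.6)]:
            s0 = np.sin(2 * np.pi * (t - 2.0) / d0)
            s1 = np.sin(2 * np.pi * (t - 2.0) / d1)
            n0 = time_normalize_stride(t, s0, 2.0, 2.0 + d0, 101)
            n1 = time_normalize_stride(t, s1, 2.0, 2.0 + d1, 101)
            assert np.max(np.abs(n0 - n1)) < 5e-3

    def test_out_of_range_raises(self):
        t = np.arange(0, 1, 0.01)
        with pytest.raises(ValueError):
            time_normalize_stride(t, t, 0.5, 2.0)
        with pytest.raises(ValueError):
            time_normalize_stride(t, t, 0.5, 0.4)
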