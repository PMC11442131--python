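"""Segment frames, Cardan XYZ decomposition, filtering, baseline."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.spatial.transform import Rotation
from scipy import signal as sps

from graspquant.kinematics import (
    AngleStream,
    BaselinePosture,
    DegenerateGeometryError,
    FilterSpec,
    GimbalLockWarning,
    apply_baseline,
    cardan_compose,
    cardan_xyz,
    compute_baseline,
    filter_zero_lag,
    joint_angles,
    segment_frame,
)

angle_80 = st.floats(min_value=-80.0, max_value=80.0)


class TestSegmentFrame:
    def test_axis_aligned_markers_give_identity(self):
        rot, origin = segment_frame([[0, 0, 0], [1, 0, 0], [0, 1, 0]])
        assert np.allclose(rot, np.eye(3), atol=1e-12)
        assert np.allclose(origin, 0.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_recovers_applied_rotation(self, seed):
        rng = np.random.default_rng(seed)
        r_true = Rotation.random(random_state=seed).as_matrix()
        template = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0.3, 0.4, 0.2]])
        shift = rng.normal(size=3)
        rot, origin = segment_frame(template @ r_true.T + shift)
        assert np.allclose(rot, r_true, atol=1e-9)
        assert np.allclose(origin, shift, atol=1e-12)

    def test_orthonormal_and_right_handed(self, rng):
        pts = rng.normal(size=(4, 3))
        rot, _ = segment_frame(pts)
        assert np.allclose(rot.T @ rot, np.eye(3), atol=1e-9)
        assert np.isclose(np.linalg.det(rot), 1.0, atol=1e-9)

    def test_collinear_markers_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            segment_frame([[0, 0, 0], [1, 1, 1], [2, 2, 2]])


class TestCardanXYZ:
    def test_identity_decomposes_to_zero(self):
        assert cardan_xyz(np.eye(3)) == (0.0, 0.0, 0.0)

    def test_pure_x_rotation(self):
        x, y, z = cardan_xyz(cardan_compose(30.0, 0.0, 0.0))
        assert np.allclose((x, y, z), (30.0, 0.0, 0.0), atol=1e-9)

    @given(x=angle_80, y=angle_80, z=angle_80)
    def test_compose_decompose_identity(self, x, y, z):
        rec = cardan_xyz(cardan_compose(x, y, z))
        assert np.allclose(rec, (x, y, z), atol=1e-6)

    def test_matches_scipy_intrinsic_xyz(self, rng):
        # independent cross-check of the composition convention
        ang = rng.uniform(-70, 70, 3)
        ours = cardan_compose(*ang)
        theirs = Rotation.from_euler("XYZ", ang, degrees=True).as_matrix()
        assert np.allclose(ours, theirs, atol=1e-12)

    def test_gimbal_lock_flagged_and_z_zeroed(self):
        r = cardan_compose(20.0, 90.0, 0.0)
        with pytest.warns(GimbalLockWarning):
            x, y, z = cardan_xyz(r)
        assert z == 0.0
        assert np.isclose(y, 90.0)

    def test_non_orthonormal_rejected(self):
        with pytest.raises(ValueError, match="orthonormal"):
            cardan_xyz(np.eye(3) * 2.0)


class TestJointAngles:
    def test_identical_frames_give_zero(self):
        r = cardan_compose(25.0, 10.0, -5.0)
        flex, abd = joint_angles(r, r)
        assert np.allclose((flex, abd), 0.0, atol=1e-9)

    def test_pure_flexion_about_joint_x(self):
        prox = cardan_compose(15.0, 0.0, 0.0)
        dist = prox @ cardan_compose(45.0, 0.0, 0.0)
        flex, abd = joint_angles(prox, dist)
        assert np.isclose(flex, 45.0, atol=1e-9)
        assert np.isclose(abd, 0.0, atol=1e-9)


class TestFilter:
    def setup_method(self):
        self.spec = FilterSpec(cutoff_hz=5.0, sampling_rate=125.0)

    def test_dc_gain_is_one(self):
        out = filter_zero_lag(np.full(500, 37.0), self.spec)
        assert np.abs(out - 37.0).max() < 1e-9

    def test_amplitude_gain_half_at_cutoff(self):
        # forward-backward 4th-order Butterworth: |H|^2 = 0.5 at cutoff
        fs, fc = 125.0, 5.0
        t = np.arange(int(fs * 60)) / fs
        x = np.sin(2 * np.pi * fc * t)
        y = filter_zero_lag(x, self.spec)
        steady = slice(len(t) // 4, 3 * len(t) // 4)
        gain = np.abs(y[steady]).max()
        assert abs(gain - 0.5) < 0.02

    def test_zero_phase_at_low_frequency(self):
        fs, f = 125.0, 0.5  # 0.1x cutoff
        t = np.arange(int(fs * 40)) / fs
        x = np.sin(2 * np.pi * f * t)
        y = filter_zero_lag(x, self.spec)
        lags = sps.correlation_lags(len(x), len(y))
        xc = sps.correlate(y - y.mean(), x - x.mean())
        assert lags[np.argmax(xc)] == 0

    def test_linearity(self, rng):
        x = rng.normal(size=400)
        y = rng.normal(size=400)
        lhs = filter_zero_lag(2.5 * x - 1.5 * y, self.spec)
        rhs = 2.5 * filter_zero_lag(x, self.spec) - 1.5 * filter_zero_lag(y, self.spec)
        assert np.abs(lhs - rhs).max() < 1e-9

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            filter_zero_lag(np.zeros(10), self.spec)

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            FilterSpec(cutoff_hz=80.0, sampling_rate=125.0)


class TestBaseline:
    def test_constant_calibration_gives_its_value(self):
        v = np.array([1.0, 2.0, 3.0, 4.0])
        stream = AngleStream("index", 125.0, np.tile(v, (125, 1)))
        baseline = compute_baseline(stream)
        assert np.allclose(baseline.zero_angles, v)

    def test_alternating_calibration_averages(self):
        frames = np.zeros((125, 4))
        frames[::2] = 2.0
        stream = AngleStream("index", 125.0, frames)
        baseline = compute_baseline(stream)
        # 63 frames of 2 and 62 of 0 -> mean 126/125
        assert np.allclose(baseline.zero_angles, 126.0 / 125.0)

    def test_short_calibration_rejected(self):
        stream = AngleStream("index", 125.0, np.zeros((100, 4)))
        with pytest.raises(ValueError, match="frames"):
            compute_baseline(stream)

    def test_apply_baseline_subtracts_framewise(self):
        stream = AngleStream("ring", 125.0, np.tile([11.0, 12, 13, 14], (200, 1)))
        baseline = BaselinePosture("ring", np.array([1.0, 2, 3, 4]))
        out = apply_baseline(stream, baseline)
        assert np.allclose(out.frames, 10.0)
        assert out.n_frames == stream.n_frames
        assert out.sampling_rate == stream.sampling_rate

    def test_apply_then_invert_is_identity(self, rng):
        frames = rng.normal(size=(50, 4))
        stream = AngleStream("little", 125.0, frames)
        baseline = BaselinePosture("little", np.array([1.0, -2, 3, -4]))
        neg = BaselinePosture("little", -baseline.zero_angles)
        out = apply_baseline(apply_baseline(stream, baseline), neg)
        assert np.abs(out.frames - frames).max() < 1e-12

    def test_finger_mismatch_rejected(self):
        stream = AngleStream("ring", 125.0, np.zeros((10, 4)))
        baseline = BaselinePosture("index", np.zeros(4))
        with pytest.raises(ValueError, match="mismatch"):
            apply_baseline(stream, baseline)
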