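import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from armkin import rotation_core as rc
from armkin.errors import (
    InvalidOrientationError,
    ParameterError,
    RankDeficiencyError,
)

SQ2 = np.sqrt(0.5)


class TestQuatMatrix:
    def test_identity(self):
        assert np.allclose(rc.quat_to_matrix([1, 0, 0, 0]), np.eye(3))

    def test_90deg_about_z(self):
        R = rc.quat_to_matrix([SQ2, 0, 0, SQ2])
        expected = np.array([[0, -1, 0], [1, 0, 0], [0, 0, 1]], dtype=float)
        assert np.allclose(R, expected, atol=1e-12)

    def test_round_trip_random(self):
        rng = np.random.default_rng(0)
        q = rng.normal(size=(1000, 4))
        q /= np.linalg.norm(q, axis=1, keepdims=True)
        for qi in q:
            R = rc.quat_to_matrix(qi)
            assert np.allclose(R.T @ R, np.eye(3), atol=1e-9)
            assert np.isclose(np.linalg.det(R), 1.0, atol=1e-9)
            q2 = rc.matrix_to_quat(R)
            assert min(np.linalg.norm(q2 - qi), np.linalg.norm(q2 + qi)) < 1e-9

    @pytest.mark.parametrize("bad", [[0, 0, 0, 0], [np.nan, 0, 0, 1], [np.inf, 0, 0, 0]])
    def test_invalid_input(self, bad):
        with pytest.raises(InvalidOrientationError):
            rc.quat_to_matrix(bad)


class TestSlerp:
    def test_endpoints(self):
        q0 = rc.canonicalize(np.array([SQ2, SQ2, 0, 0]))
        q1 = rc.canonicalize(np.array([SQ2, 0, SQ2, 0]))
        assert np.allclose(rc.slerp(q0, q1, 0.0), q0, atol=1e-12)
        assert np.allclose(rc.slerp(q0, q1, 1.0), q1, atol=1e-12)

    def test_halfway_90deg_about_x(self):
        q0 = np.array([1.0, 0, 0, 0])
        q1 = np.array([SQ2, SQ2, 0, 0])  # 90 deg about X
        mid = rc.slerp(q0, q1, 0.5)
        expected = np.array([np.cos(np.pi / 8), np.sin(np.pi / 8), 0, 0])
        assert np.allclose(mid, expected, atol=1e-12)

    def test_quarter_angle_matrix_log_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            r0, r1 = Rotation.random(2, rng=rng)
            q0 = rc.canonicalize(r0.as_quat(scalar_first=True))
            q1 = rc.canonicalize(r1.as_quat(scalar_first=True))
            out = rc.slerp(q0, q1, 0.25)
            # matrix-log oracle: geodesic angle from q0 to out vs q0 to q1
            full = (r0.inv() * Rotation.from_quat(q1, scalar_first=True)).magnitude()
            part = (
                r0.inv() * Rotation.from_quat(out, scalar_first=True)
            ).magnitude()
            assert np.isclose(part, 0.25 * min(full, 2 * np.pi - full), atol=1e-10)

    def test_output_unit_norm_sweep(self):
        rng = np.random.default_rng(4)
        for _ in range(100):
            q = rng.normal(size=(2, 4))
            q /= np.linalg.norm(q, axis=1, keepdims=True)
            out = rc.slerp(q[0], q[1], rng.random())
            assert abs(np.linalg.norm(out) - 1.0) < 1e-12

    def test_t_out_of_range(self):
        with pytest.raises(ParameterError):
            rc.slerp([1, 0, 0, 0], [1, 0, 0, 0], 1.5)


class TestSlerpSmooth:
    def test_constant_series_fixed_point(self):
        q = np.tile(rc.canonicalize([SQ2, 0, SQ2, 0]), (20, 1))
        out = rc.slerp_smooth(q, alpha=0.3)
        assert np.allclose(out, q, atol=1e-12)

    def test_alpha_one_identity(self):
        rng = np.random.default_rng(5)
        q = rng.normal(size=(15, 4))
        q /= np.linalg.norm(q, axis=1, keepdims=True)
        q[q[:, 0] < 0] *= -1
        out = rc.slerp_smooth(q, alpha=1.0)
        assert np.allclose(out, q, atol=1e-12)

    def test_reduces_noise_rms(self):
        # noisy samples around a fixed rotation: smoothing must shrink the RMS
        # angular deviation from the true rotation
        rng = np.random.default_rng(6)
        truth = Rotation.from_euler("YXY", [40, 60, -20], degrees=True)
        noisy = (
            Rotation.from_rotvec(rng.normal(0, np.radians(5.0), size=(200, 3))) * truth
        )
        q = noisy.as_quat(scalar_first=True)
        out = rc.slerp_smooth(q, alpha=0.3)
        def rms_dev(quats):
            rots = Rotation.from_quat(quats, scalar_first=True)
            return np.sqrt(np.mean((truth.inv() * rots).magnitude() ** 2))
        assert rms_dev(out) < rms_dev(q)

    @pytest.mark.parametrize("alpha", [0.0, -0.1, 1.5])
    def test_alpha_domain(self, alpha):
        with pytest.raises(ParameterError):
            rc.slerp_smooth(np.array([[1.0, 0, 0, 0]]), alpha)


class TestEulerIntrinsic:
    def test_identity(self):
        angles, degenerate = rc.euler_intrinsic(np.eye(3), "YXY")
        assert degenerate  # a2 = 0 is the gimbal configuration
        assert np.allclose(angles, 0.0)

    def test_compose_decompose_round_trip(self):
        R = rc.compose_euler("YXY", [30, 45, -20])
        angles, degenerate = rc.euler_intrinsic(R, "YXY")
        assert not degenerate
        assert np.allclose(angles, [30, 45, -20], atol=1e-10)

    def test_gimbal_convention(self):
        R = rc.compose_euler("YXY", [25, 0, 17])
        angles, degenerate = rc.euler_intrinsic(R, "YXY")
        assert degenerate
        assert np.isclose(angles[2], 0.0)
        assert np.isclose(angles[0], 42.0, atol=1e-9)  # a1 carries the free sum

    def test_middle_angle_ranges(self):
        rng = np.random.default_rng(7)
        for R in Rotation.random(200, rng=rng):
            sym, _ = rc.euler_intrinsic(R.as_matrix(), "YXY")
            asym, _ = rc.euler_intrinsic(R.as_matrix(), "ZXY")
            assert 0.0 <= sym[1] <= 180.0
            assert -90.0 <= asym[1] <= 90.0

    def test_bad_sequence(self):
        with pytest.raises(ParameterError):
            rc.euler_intrinsic(np.eye(3), "YYX")


class TestUnwrap:
    def test_single_wrap(self):
        out = rc.unwrap_angles([179.0, -179.0])
        assert np.allclose(out, [179.0, 181.0])

    def test_constant_unchanged(self):
        out = rc.unwrap_angles(np.full(10, 33.0))
        assert np.allclose(out, 33.0)

    def test_sawtooth_ramp_recovered(self):
        ramp = np.linspace(0.0, 720.0, 400)
        wrapped = (ramp + 180.0) % 360.0 - 180.0
        out = rc.unwrap_angles(wrapped)
        assert np.allclose(out - out[0], ramp, atol=1e-9)

    @settings(derandomize=True, max_examples=30)
    @given(
        st.lists(st.floats(min_value=-1e4, max_value=1e4), min_size=1, max_size=50)
    )
    def test_idempotent_and_congruent(self, values):
        x = np.asarray(values)
        once = rc.unwrap_angles(x)
        assert np.allclose(rc.unwrap_angles(once), once, atol=1e-9)
        assert np.allclose((once - x + 180.0) % 360.0, 180.0, atol=1e-6)
        assert np.all(np.abs(np.diff(once)) <= 180.0 + 1e-9)

    def test_empty(self):
        assert rc.unwrap_angles([]).size == 0


class TestRotationCenter:
    @staticmethod
    def _sweep(center, n_frames, rng, noise_sd=0.0):
        offsets = np.array([[120.0, 30.0, 10.0], [60.0, -80.0, 40.0], [0.0, 90.0, -70.0]])
        rots = Rotation.random(n_frames, rng=rng)
        pts = np.stack([rots.apply(o) for o in offsets], axis=1) + center
        if noise_sd:
            pts = pts + rng.normal(0, noise_sd, size=pts.shape)
        return pts

    def test_noise_free_exact(self):
        rng = np.random.default_rng(8)
        pts = self._sweep(np.array([100.0, 50.0, 0.0]), 50, rng)
        centre, resid = rc.estimate_rotation_center(pts)
        assert np.allclose(centre, [100.0, 50.0, 0.0], atol=1e-6)
        assert resid < 1e-6

    def test_noisy_within_1mm(self):
        rng = np.random.default_rng(9)
        pts = self._sweep(np.array([100.0, 50.0, 0.0]), 500, rng, noise_sd=1.0)
        centre, _ = rc.estimate_rotation_center(pts)
        assert np.linalg.norm(centre - np.array([100.0, 50.0, 0.0])) < 1.0

    def test_static_frames_rank_deficient(self):
        pts = np.tile(np.array([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]]), (20, 1, 1))
        with pytest.raises(RankDeficiencyError):
            rc.estimate_rotation_center(pts)

    def test_too_few_frames(self):
        with pytest.raises(RankDeficiencyError):
            rc.estimate_rotation_center(np.zeros((5, 2, 3)))
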