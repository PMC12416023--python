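import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from armkin.angle_methods import (
    IKSettings,
    align_tables,
    build_difference_sets,
    cf_joint_angles,
    compute_reference_angles,
    ik_joint_angles,
)
from armkin.errors import MissingSegmentError, ParameterError
from armkin.series import ANGLE_CHANNELS, JointAngleTable, OrientationSeries
from armkin.synthetic_data import (
    MOVEMENT_NAMES,
    NoiseSpec,
    generate_movement,
    simulate_markerless,
    simulate_reference,
)

CH = list(ANGLE_CHANNELS)


def _truth_errors(table, script):
    truth = script.sample(table.times)
    cols = {
        "shoulder_plane_of_elevation": 0,
        "shoulder_angle_of_elevation": 1,
        "shoulder_rotation": 2,
        "elbow_flexion": 3,
        "pronation": 4,
    }
    return {
        ch: float(np.abs(table.channels[ch] - truth[:, cols[ch]]).max())
        for ch in table.channels
    }


class TestCFMethod:
    def test_identity_orientations_zero_angles(self):
        n = 40
        quats = np.zeros((n, 3, 4))
        quats[:, :, 0] = 1.0
        ors = OrientationSeries(
            times=np.arange(n) / 30.0, segments=("thorax", "humerus", "forearm"),
            quats=quats, rate=30.0,
        )
        table = cf_joint_angles(ors, target_rate=None)
        for ch in CH:
            assert np.allclose(table.channels[ch], 0.0, atol=1e-9)

    def test_noise_free_recovery(self, model):
        script = generate_movement("shoulder_abduction")
        _, ors = simulate_markerless(script, model, 30.0, NoiseSpec())
        table = cf_joint_angles(ors, smoothing_alpha=1.0, target_rate=None)
        errs = _truth_errors(table, script)
        assert max(errs.values()) < 1e-6

    def test_device_offsets_cancelled_by_realignment(self, model):
        script = generate_movement("brush_hair")
        rng = np.random.default_rng(31)
        offsets = {}
        realign = {}
        for seg in ("thorax", "humerus", "forearm"):
            r = Rotation.random(rng=rng)
            offsets[seg] = tuple(r.as_quat(scalar_first=True))
            realign[seg] = r.as_matrix().T
        _, ors_off = simulate_markerless(
            script, model, 30.0, NoiseSpec(frame_offsets=offsets)
        )
        _, ors_plain = simulate_markerless(script, model, 30.0, NoiseSpec())
        t_off = cf_joint_angles(ors_off, realignment=realign, smoothing_alpha=1.0)
        t_plain = cf_joint_angles(ors_plain, smoothing_alpha=1.0)
        for ch in CH:
            assert np.abs(t_off.channels[ch] - t_plain.channels[ch]).max() < 1e-6

    def test_missing_segment(self):
        n = 10
        quats = np.zeros((n, 2, 4))
        quats[:, :, 0] = 1.0
        ors = OrientationSeries(
            times=np.arange(n) / 30.0, segments=("thorax", "humerus"),
            quats=quats, rate=30.0,
        )
        with pytest.raises(MissingSegmentError, match="forearm"):
            cf_joint_angles(ors)

    def test_upsamples_to_120(self, model):
        script = generate_movement("elbow_flexion")
        _, ors = simulate_markerless(script, model, 30.0, NoiseSpec())
        table = cf_joint_angles(ors, smoothing_alpha=1.0, target_rate=120.0)
        assert table.rate == 120.0
        assert len(table) == (len(ors) - 1) * 4 + 1


class TestIKMethod:
    def test_noise_free_recovery_elbow_flexion(self, model):
        script = generate_movement("elbow_flexion")
        kp, _ = simulate_markerless(script, model, 30.0, NoiseSpec())
        table = ik_joint_angles(kp, model, IKSettings(), filter_spec=False, target_rate=None)
        errs = _truth_errors(table, script)
        assert errs["elbow_flexion"] < 0.1
        assert max(errs.values()) < 0.1

    def test_exact_keypoints_zero_objective(self, model):
        script = generate_movement("drink_from_cup")
        kp, _ = simulate_markerless(script, model, 30.0, NoiseSpec())
        table = ik_joint_angles(kp, model, IKSettings(), filter_spec=False, target_rate=None)
        assert table.meta["ik_max_objective_mm2"] < 1e-10

    def test_noisy_rmse_within_sanity_band(self, model):
        # 5 mm keypoint noise on a planar task: RMSE of the driven channel
        # must sit in the band recorded from the noise-propagation oracle
        # (clearly above zero, clearly below gross failure; the 5 Hz
        # pre-filter removes most of the raw keypoint noise)
        script = generate_movement("shoulder_abduction")
        kp, _ = simulate_markerless(
            script, model, 30.0, NoiseSpec(keypoint_sd_mm=5.0),
            rng=np.random.default_rng(41),
        )
        table = ik_joint_angles(kp, model, IKSettings(), target_rate=None)
        truth = script.sample(kp.times)
        rmse = float(
            np.sqrt(np.mean((table.channels["shoulder_angle_of_elevation"] - truth[:, 1]) ** 2))
        )
        assert 0.1 < rmse < 10.0
        assert table.meta["ik_max_objective_mm2"] > 0.0

    def test_objective_non_increasing_per_frame(self, model):
        script = generate_movement("perineal_care")
        kp, _ = simulate_markerless(
            script, model, 30.0, NoiseSpec(keypoint_sd_mm=8.0),
            rng=np.random.default_rng(42),
        )
        table = ik_joint_angles(
            kp, model, IKSettings(track_costs=True), target_rate=None
        )
        traces = table.meta["ik_cost_traces"]
        assert len(traces) > 0
        for trace in traces:
            assert all(b <= a + 1e-9 for a, b in zip(trace, trace[1:]))

    def test_kernel_matches_reference_path(self, model):
        script = generate_movement("collect_change")
        kp, _ = simulate_markerless(
            script, model, 30.0, NoiseSpec(keypoint_sd_mm=5.0),
            rng=np.random.default_rng(43),
        )
        fast = ik_joint_angles(kp, model, IKSettings(), target_rate=None)
        slow = ik_joint_angles(kp, model, IKSettings(track_costs=True), target_rate=None)
        for ch in CH:
            assert np.abs(fast.channels[ch] - slow.channels[ch]).max() < 1e-6

    def test_final_poses_within_limits(self, model):
        script = generate_movement("brush_hair")
        kp, _ = simulate_markerless(
            script, model, 30.0, NoiseSpec(keypoint_sd_mm=15.0),
            rng=np.random.default_rng(44),
        )
        table = ik_joint_angles(kp, model, IKSettings(), target_rate=None)
        lim = model.limits
        assert table.channels["shoulder_angle_of_elevation"].min() >= lim["shoulder_elev"][0] - 1e-9
        assert table.channels["shoulder_angle_of_elevation"].max() <= lim["shoulder_elev"][1] + 1e-9
        assert table.channels["elbow_flexion"].min() >= lim["elbow_flex"][0] - 1e-9
        assert table.channels["elbow_flexion"].max() <= lim["elbow_flex"][1] + 1e-9

    def test_misdetected_frames_interpolated(self, model):
        script = generate_movement("shoulder_abduction")
        kp, _ = simulate_markerless(script, model, 30.0, NoiseSpec())
        # knock out elbow AND wrist over a short stretch: frames unresolved
        kp.valid[100:105, kp.index("elbow")] = False
        kp.valid[100:105, kp.index("wrist")] = False
        table = ik_joint_angles(kp, model, IKSettings(), filter_spec=False, target_rate=None)
        assert table.meta["ik_unresolved_frames"] == 5
        truth = script.sample(kp.times)
        # interpolation across 5 frames of a smooth trajectory stays close
        assert np.abs(
            table.channels["shoulder_angle_of_elevation"] - truth[:, 1]
        ).max() < 1.0

    def test_cf_and_ik_agree_noise_free(self, model):
        for name in ("shoulder_abduction", "eat_with_spoon"):
            script = generate_movement(name)
            kp, ors = simulate_markerless(script, model, 30.0, NoiseSpec())
            cf = cf_joint_angles(ors, smoothing_alpha=1.0, target_rate=None)
            ik = ik_joint_angles(kp, model, IKSettings(), filter_spec=False, target_rate=None)
            for ch in CH:
                keep = ~(cf.gimbal_flag | ik.gimbal_flag)
                assert np.abs(cf.channels[ch][keep] - ik.channels[ch][keep]).max() < 0.5


class TestReferenceAngles:
    def test_rate_preserved(self, model):
        script = generate_movement("elbow_flexion")
        kp, _, _ = simulate_reference(script, model, 120.0, NoiseSpec())
        table = compute_reference_angles(kp, model)
        assert table.rate == 120.0
        assert len(table) == len(kp)

    def test_noise_free_matches_truth(self, model):
        script = generate_movement("elbow_flexion")
        kp, _, _ = simulate_reference(script, model, 120.0, NoiseSpec())
        table = compute_reference_angles(kp, model, filter_spec=False)
        errs = _truth_errors(table, script)
        assert max(errs.values()) < 0.1

    def test_low_noise_rmse_bounded(self, model):
        script = generate_movement("shoulder_abduction")
        kp, _, _ = simulate_reference(
            script, model, 120.0, NoiseSpec(keypoint_sd_mm=0.5),
            rng=np.random.default_rng(45),
        )
        table = compute_reference_angles(kp, model)
        truth = script.sample(kp.times)
        rmse = float(np.sqrt(np.mean((table.channels["shoulder_angle_of_elevation"] - truth[:, 1]) ** 2)))
        assert rmse < 0.5  # noise-matched bound from the propagation oracle


class TestAlignmentAndDifferences:
    def _tables(self, model, latency=0.15):
        script = generate_movement("shoulder_abduction")
        kp, _, _ = simulate_reference(script, model, 120.0, NoiseSpec())
        ref = compute_reference_angles(kp, model)
        mkp, _ = simulate_markerless(script, model, 30.0, NoiseSpec(latency_s=latency))
        ik = ik_joint_angles(mkp, model, IKSettings(), target_rate=120.0)
        return ik, ref

    def test_latency_recovered_and_removed(self, model):
        ik, ref = self._tables(model)
        t_al, r_al, lag = align_tables(ik, ref)
        assert lag == 18  # 0.15 s at 120 Hz
        diffs = build_difference_sets(t_al, r_al)
        assert np.abs(diffs["shoulder_angle_of_elevation"]).max() < 0.5

    def test_identical_tables_zero_differences(self, model):
        ik, _ = self._tables(model, latency=0.0)
        diffs = build_difference_sets(ik, ik)
        assert set(diffs) == set(ANGLE_CHANNELS)
        for arr in diffs.values():
            assert np.allclose(arr, 0.0)

    def test_constant_offset_propagates(self, model):
        ik, _ = self._tables(model, latency=0.0)
        shifted = JointAngleTable(
            times=ik.times, rate=ik.rate,
            channels={
                ch: v + (5.0 if ch == "elbow_flexion" else 0.0)
                for ch, v in ik.channels.items()
            },
            meta=dict(ik.meta), gimbal_flag=ik.gimbal_flag,
        )
        diffs = build_difference_sets(shifted, ik)
        assert np.allclose(diffs["elbow_flexion"], 5.0)
        assert np.allclose(diffs["shoulder_rotation"], 0.0)

    def test_rate_mismatch_rejected(self, model):
        ik, ref = self._tables(model)
        bad = JointAngleTable(
            times=np.arange(100) / 30.0, rate=30.0,
            channels={ch: np.zeros(100) for ch in ANGLE_CHANNELS},
        )
        with pytest.raises(ParameterError):
            align_tables(bad, ref)


class TestAngleSeriesView:
    def test_channel_view_carries_rate_and_label(self, model):
        script = generate_movement("elbow_flexion")
        _, ors = simulate_markerless(script, model, 30.0, NoiseSpec())
        table = cf_joint_angles(ors, smoothing_alpha=1.0, target_rate=120.0)
        series = table.channel("elbow_flexion")
        assert series.rate == 120.0
        assert series.label == "elbow_flexion"
        assert len(series) == len(table)
        assert np.array_equal(series.values, table.channels["elbow_flexion"])

    def test_inconsistent_timestamps_rejected(self):
        from armkin.series import AngleSeries

        with pytest.raises(ParameterError):
            AngleSeries(times=np.array([0.0, 0.5, 1.0]), values=np.zeros(3), rate=30.0)
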