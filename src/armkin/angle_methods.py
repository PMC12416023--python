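"""The two joint-angle computation methods compared by the pipeline.

Coordinate-frame (CF) method
    Segment orientations (quaternions) are smoothed on the rotation manifold,
    converted to rotation matrices, realigned from the device's segment-frame
    conventions to the anatomical ones, combined into joint rotations
    (``R_joint = R_proximal^T R_distal``), decomposed into intrinsic Euler
    angles (shoulder Y-X-Y, elbow Z-X-Y with flexion leading), unwrapped and
    upsampled to the reference rate.

Inverse-kinematics (IK) method
    Keypoints scale a template limb model, are low-pass filtered, and each
    frame's pose is found by bounded nonlinear least squares: minimise the
    weighted squared distance between the model's virtual keypoints and the
    measured ones, warm-started from the previous frame. A tiny proximal
    penalty toward the previous solution makes the plane-of-elevation /
    axial-rotation split deterministic near the shoulder gimbal
    configuration. Angles are computed at the native keypoint rate and
    upsampled afterwards.

The reference channel uses the same IK machinery at its own rate and filter
settings, without upsampling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import (
    InsufficientDataError,
    MissingSegmentError,
    ParameterError,
    UndefinedCorrelationError,
)
from .limb_model import (
    DOF_NAMES,
    LimbModel,
    scale_model_from_keypoints,
)
from .rotation_core import euler_intrinsic_batch, slerp_smooth, unwrap_angles
from .series import (
    ANGLE_CHANNELS,
    JointAngleTable,
    KeypointSeries,
    OrientationSeries,
)
from .signal_prep import (
    FilterSpec,
    butterworth_zero_phase,
    cross_correlation_align,
    resample_scalar,
)

__all__ = [
    "IKSettings",
    "cf_joint_angles",
    "ik_joint_angles",
    "compute_reference_angles",
    "align_tables",
    "build_difference_sets",
]

# neutral pose used to start the first frame's optimisation (deg)
NEUTRAL_POSE = np.array([0.0, 5.0, 0.0, 5.0, 0.0])

_SHOULDER_CHANNELS = (
    "shoulder_plane_of_elevation",
    "shoulder_angle_of_elevation",
    "shoulder_rotation",
)


@dataclass
class IKSettings:
    """Solver configuration for the inverse-kinematics method."""

    weights: dict[str, float] | None = None  # keypoint -> weight, None = equal
    pronation_locked: bool = True
    thumb_excluded: bool = True
    tolerance: float = 1e-16  # convergence on squared-step size (deg^2)
    gradient_tolerance: float = 1e-10  # convergence on the cost gradient (mm^2/deg)
    max_iterations: int = 100
    warm_start: bool = True
    gimbal_lambda: float = 1e-6  # proximal penalty weight (mm^2/deg^2)
    track_costs: bool = False

    def __post_init__(self):
        if self.tolerance <= 0:
            raise ParameterError("tolerance must be positive")
        if self.weights is not None and any(w < 0 for w in self.weights.values()):
            raise ParameterError("keypoint weights must be >= 0")


# ---------------------------------------------------------------------------
# coordinate-frame method
# ---------------------------------------------------------------------------


def _quats_to_matrices(quats: np.ndarray) -> np.ndarray:
    from scipy.spatial.transform import Rotation

    return Rotation.from_quat(quats, scalar_first=True).as_matrix()


def cf_joint_angles(
    orientations: OrientationSeries,
    realignment: dict[str, np.ndarray] | None = None,
    smoothing_alpha: float = 1.0,
    target_rate: float | None = 120.0,
    gimbal_band_deg: float = 1.0,
    include_pronation: bool = False,
    meta: dict | None = None,
) -> JointAngleTable:
    """Joint angles from segment orientation frames.

    ``realignment`` maps segment name to a 3x3 rotation post-multiplied onto
    the measured segment orientation to undo a constant device-convention
    frame offset (identity if omitted).
    """
    for seg in ("thorax", "humerus", "forearm"):
        if seg not in orientations.segments:
            raise MissingSegmentError(f"orientation series lacks segment {seg!r}")

    mats = {}
    for seg in ("thorax", "humerus", "forearm"):
        q = slerp_smooth(orientations.get(seg), smoothing_alpha)
        R = _quats_to_matrices(q)
        if realignment and seg in realignment:
            A = np.asarray(realignment[seg], dtype=float)
            R = R @ A
        mats[seg] = R

    R_sh = np.einsum("nji,njk->nik", mats["thorax"], mats["humerus"])
    R_el = np.einsum("nji,njk->nik", mats["humerus"], mats["forearm"])
    sh, near_gimbal = euler_intrinsic_batch(R_sh, "YXY", band_deg=gimbal_band_deg)
    el, _ = euler_intrinsic_batch(R_el, "ZXY", band_deg=gimbal_band_deg)

    channels = {
        "shoulder_plane_of_elevation": unwrap_angles(sh[:, 0]),
        "shoulder_angle_of_elevation": unwrap_angles(sh[:, 1]),
        "shoulder_rotation": unwrap_angles(sh[:, 2]),
        "elbow_flexion": unwrap_angles(el[:, 0]),
    }
    if include_pronation:
        channels["pronation"] = unwrap_angles(el[:, 2])

    rate = orientations.rate
    times = orientations.times
    flag = near_gimbal
    if target_rate is not None and target_rate != rate:
        channels = {k: resample_scalar(v, rate, target_rate) for k, v in channels.items()}
        r = int(round(target_rate / rate))
        m = (len(times) - 1) * r + 1
        idx = np.clip(np.round(np.arange(m) / r).astype(int), 0, len(flag) - 1)
        flag = flag[idx]
        times = np.arange(m) / target_rate + times[0]
        rate = target_rate

    meta = dict(meta or {})
    meta.setdefault("method", "CF")
    return JointAngleTable(
        times=times, rate=rate, channels=channels, meta=meta, gimbal_flag=flag
    )


# ---------------------------------------------------------------------------
# inverse-kinematics method
# ---------------------------------------------------------------------------


def _interpolate_invalid(points: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Replace invalid samples of each keypoint coordinate by linear
    interpolation over time (edge values held)."""
    out = points.copy()
    n = points.shape[0]
    t = np.arange(n, dtype=float)
    for m in range(points.shape[1]):
        ok = valid[:, m]
        if ok.all():
            continue
        if not ok.any():
            continue  # nothing to anchor on; weights will be zero anyway
        for c in range(3):
            out[~ok, m, c] = np.interp(t[~ok], t[ok], points[ok, m, c])
    return out


def _frame_kinematics(model: LimbModel, q: np.ndarray):
    """Positions of elbow/wrist/hand plus the world joint axes at pose ``q``
    (deg). Returns (positions dict, axes (5, 3), origins (5, 3))."""
    p, e, r, f, pr = np.radians(q)
    cp_, sp_ = math.cos(p), math.sin(p)
    ce, se = math.cos(e), math.sin(e)
    cr, sr = math.cos(r), math.sin(r)
    cf_, sf_ = math.cos(f), math.sin(f)
    cpr, spr = math.cos(pr), math.sin(pr)
    Ry_p = np.array([[cp_, 0, sp_], [0, 1, 0], [-sp_, 0, cp_]])
    Rx_e = np.array([[1, 0, 0], [0, ce, -se], [0, se, ce]])
    Ry_r = np.array([[cr, 0, sr], [0, 1, 0], [-sr, 0, cr]])
    Rz_f = np.array([[cf_, -sf_, 0], [sf_, cf_, 0], [0, 0, 1]])
    Ry_pr = np.array([[cpr, 0, spr], [0, 1, 0], [-spr, 0, cpr]])
    R_h = Ry_p @ Rx_e @ Ry_r
    R_hf = R_h @ Rz_f
    R_f = R_hf @ Ry_pr

    shoulder = np.asarray(model.clavicle_offset, dtype=float)
    elbow = shoulder + R_h @ np.array([0.0, -model.humerus_length, 0.0])
    wrist = elbow + R_f @ np.array([0.0, -model.forearm_length, 0.0])
    hand = wrist + R_f @ np.asarray(model.hand_offset, dtype=float)

    axes = np.empty((5, 3))
    axes[0] = [0.0, 1.0, 0.0]
    axes[1] = Ry_p[:, 0]
    axes[2] = R_h[:, 1]
    axes[3] = R_h[:, 2]
    axes[4] = R_hf[:, 1]
    origins = np.empty((5, 3))
    origins[0] = origins[1] = origins[2] = shoulder
    origins[3] = origins[4] = elbow
    positions = {"shoulder": shoulder, "elbow": elbow, "wrist": wrist, "hand": hand}
    return positions, axes, origins


def _analytic_pose(model: LimbModel, elbow: np.ndarray, wrist: np.ndarray) -> np.ndarray:
    """Closed-form pose estimate from elbow and wrist positions.

    Inverts the chain geometry directly (elevation/plane from the upper-arm
    direction, axial rotation and flexion from the forearm direction in the
    humerus frame); pronation is unobservable from these points and set to 0.
    Used to start the first frame's optimisation so the warm-start chain
    begins near the global minimum even for trials that start far from the
    neutral posture.
    """
    shoulder = np.asarray(model.clavicle_offset, dtype=float)
    d = elbow - shoulder
    nd = np.linalg.norm(d)
    if nd < 1e-9:
        return NEUTRAL_POSE.copy()
    d = d / nd
    e = math.degrees(math.acos(min(1.0, max(-1.0, -d[1]))))
    if math.hypot(d[0], d[2]) > 1e-9:
        p = math.degrees(math.atan2(-d[0], -d[2]))
    else:
        p = 0.0
    u = wrist - elbow
    nu = np.linalg.norm(u)
    if nu < 1e-9:
        return np.array([p, e, 0.0, 5.0, 0.0])
    u = u / nu
    pr_, er_ = math.radians(p), math.radians(e)
    Ry_p = np.array(
        [[math.cos(pr_), 0, math.sin(pr_)], [0, 1, 0], [-math.sin(pr_), 0, math.cos(pr_)]]
    )
    Rx_e = np.array(
        [[1, 0, 0], [0, math.cos(er_), -math.sin(er_)], [0, math.sin(er_), math.cos(er_)]]
    )
    v = (Ry_p @ Rx_e).T @ u
    f = math.degrees(math.acos(min(1.0, max(-1.0, -v[1]))))
    if math.sin(math.radians(f)) > 1e-6:
        r = math.degrees(math.atan2(-v[2], v[0]))
    else:
        r = 0.0
    return np.array([p, e, r, f, 0.0])


_MOVING_KP = ("elbow", "wrist", "hand")
# which DOFs move each keypoint (indices into DOF_NAMES)
_KP_DOFS = {"elbow": (0, 1, 2), "wrist": (0, 1, 2, 3), "hand": (0, 1, 2, 3, 4)}
_DEG = math.pi / 180.0


def _solve_frame(
    model: LimbModel,
    targets: dict[str, np.ndarray],
    weights: dict[str, float],
    q_start: np.ndarray,
    q_prev: np.ndarray,
    free_idx: np.ndarray,
    lo: np.ndarray,
    hi: np.ndarray,
    settings: IKSettings,
    cost_trace: list | None = None,
):
    """Damped Gauss-Newton with bound clipping for a single frame.

    Residuals are sqrt(weight) * (model keypoint - measured keypoint) in mm
    plus a proximal row sqrt(lambda) * (q - q_prev) per free DOF. Only steps
    that decrease the cost are accepted, so the objective is non-increasing
    over iterations.
    """
    q = q_start.copy()
    used = [(k, weights[k]) for k in _MOVING_KP if weights.get(k, 0.0) > 0 and k in targets]
    sqrt_lam = math.sqrt(settings.gimbal_lambda)
    nf = len(free_idx)

    def residual_and_jac(qv):
        pos, axes, origins = _frame_kinematics(model, qv)
        r = np.empty(3 * len(used) + nf)
        J = np.zeros((3 * len(used) + nf, nf))
        row = 0
        for name, w in used:
            sw = math.sqrt(w)
            pnt = pos[name]
            r[row : row + 3] = sw * (pnt - targets[name])
            move = _KP_DOFS[name]
            for col, dof_i in enumerate(free_idx):
                if dof_i in move:
                    J[row : row + 3, col] = (
                        sw * _DEG * np.cross(axes[dof_i], pnt - origins[dof_i])
                    )
            row += 3
        r[row:] = sqrt_lam * (qv[free_idx] - q_prev[free_idx])
        J[row:, :] = sqrt_lam * np.eye(nf)
        return r, J

    r, J = residual_and_jac(q)
    cost = float(r @ r)
    if cost_trace is not None:
        cost_trace.append(cost)
    mu = 1e-4
    n_iter = 0
    for _ in range(settings.max_iterations):
        n_iter += 1
        g = J.T @ r
        if float(np.abs(g).max()) < settings.gradient_tolerance:
            break
        H = J.T @ J
        accepted = False
        for _ in range(20):
            try:
                step = np.linalg.solve(H + mu * np.eye(nf), -g)
            except np.linalg.LinAlgError:
                mu *= 10.0
                continue
            q_new = q.copy()
            q_new[free_idx] = np.clip(q[free_idx] + step, lo, hi)
            r_new, J_new = residual_and_jac(q_new)
            cost_new = float(r_new @ r_new)
            if cost_new <= cost:
                accepted = True
                step_sq = float(np.sum((q_new[free_idx] - q[free_idx]) ** 2))
                q, r, J, cost = q_new, r_new, J_new, cost_new
                if cost_trace is not None:
                    cost_trace.append(cost)
                mu = max(mu * 0.1, 1e-12)
                break
            mu *= 4.0
        if not accepted or step_sq < settings.tolerance or cost < 1e-14:
            break
    # report the keypoint objective without the proximal regularisation term
    penalty = settings.gimbal_lambda * float(
        np.sum((q[free_idx] - q_prev[free_idx]) ** 2)
    )
    return q, max(cost - penalty, 0.0), n_iter


def _default_weights(keypoints: KeypointSeries, settings: IKSettings) -> dict[str, float]:
    if settings.weights is not None:
        w = dict(settings.weights)
    else:
        w = {name: 1.0 for name in keypoints.names}
    if settings.thumb_excluded:
        w["hand"] = 0.0
    return w


def ik_joint_angles(
    keypoints: KeypointSeries,
    model: LimbModel,
    settings: IKSettings | None = None,
    filter_spec: "FilterSpec | None | bool" = None,
    target_rate: float | None = 120.0,
    gimbal_band_deg: float = 1.0,
    meta: dict | None = None,
) -> JointAngleTable:
    """Joint angles by per-frame bounded nonlinear least squares.

    The template ``model`` is first scaled from the recorded keypoint
    distances, keypoint coordinates are low-pass filtered (invalid samples are
    interpolated before filtering and given zero weight in the fit), each
    frame is solved warm-started from the previous one, and the resulting
    angle channels are unwrapped and upsampled to ``target_rate``.
    """
    settings = settings or IKSettings()
    if filter_spec is None:
        filter_spec = FilterSpec(order=4, cutoff_hz=5.0, rate_hz=keypoints.rate)
    for name in ("shoulder", "elbow", "wrist"):
        if name not in keypoints.names:
            raise MissingSegmentError(f"keypoint series lacks {name!r}")

    fitted = scale_model_from_keypoints(model, keypoints)
    if settings.pronation_locked:
        fitted = fitted.with_lock("pronation")

    pts = _interpolate_invalid(keypoints.points, keypoints.valid)
    if filter_spec is not False:  # pass False to skip filtering entirely
        flat = pts.reshape(len(keypoints), -1)
        flat = butterworth_zero_phase(flat, filter_spec, axis=0)
        pts = flat.reshape(pts.shape)

    base_w = _default_weights(keypoints, settings)
    if sum(1 for v in base_w.values() if v > 0) < 3:
        raise ParameterError("at least 3 keypoints must have positive weight")

    free_dofs = fitted.free_dofs
    free_idx = np.array([DOF_NAMES.index(d) for d in free_dofs])
    lo = np.array([fitted.limits[d][0] for d in free_dofs])
    hi = np.array([fitted.limits[d][1] for d in free_dofs])

    n = len(keypoints)
    kp_idx = {name: keypoints.index(name) for name in keypoints.names}

    # per-frame usability: weighted + valid keypoints, and at least one of the
    # keypoints that actually moves with the arm
    valid_w = np.zeros((n, len(keypoints.names)))
    for name, w in base_w.items():
        j = kp_idx[name]
        valid_w[:, j] = w * keypoints.valid[:, j]
    usable_counts = (valid_w > 0).sum(axis=1)
    moving_w = np.zeros((n, 3))
    for k, name in enumerate(_MOVING_KP):
        if name in kp_idx:
            moving_w[:, k] = valid_w[:, kp_idx[name]]
    moving_ok = (moving_w[:, 0] > 0) | (moving_w[:, 1] > 0)
    unresolved = (usable_counts < 3) | ~moving_ok
    solve_mask = ~unresolved

    targets = np.zeros((n, 3, 3))
    for k, name in enumerate(_MOVING_KP):
        if name in kp_idx:
            targets[:, k, :] = pts[:, kp_idx[name], :]

    # start the first resolved frame from a closed-form geometric estimate
    q_neutral = NEUTRAL_POSE.copy()
    first = np.flatnonzero(solve_mask & (moving_w[:, 0] > 0) & (moving_w[:, 1] > 0))
    if len(first):
        i0 = int(first[0])
        q_neutral = _analytic_pose(fitted, targets[i0, 0], targets[i0, 1])
    q_neutral[free_idx] = np.clip(q_neutral[free_idx], lo, hi)
    q_neutral[[i for i in range(len(DOF_NAMES)) if i not in free_idx]] = 0.0

    cost_traces = [] if settings.track_costs else None
    if cost_traces is None:
        from ._ik_kernel import solve_trial

        poses, objectives, iters = solve_trial(
            targets,
            moving_w,
            solve_mask,
            np.asarray(fitted.clavicle_offset, dtype=float),
            float(fitted.humerus_length),
            float(fitted.forearm_length),
            np.asarray(fitted.hand_offset, dtype=float),
            q_neutral,
            free_idx.astype(np.int64),
            lo.astype(float),
            hi.astype(float),
            float(settings.gimbal_lambda),
            float(settings.tolerance),
            float(settings.gradient_tolerance),
            int(settings.max_iterations),
            bool(settings.warm_start),
        )
    else:
        # readable reference path (also used when tracking objective traces)
        poses = np.zeros((n, len(DOF_NAMES)))
        objectives = np.zeros(n)
        iters = np.zeros(n, dtype=int)
        q_prev = q_neutral.copy()
        for i in range(n):
            if unresolved[i]:
                poses[i] = q_prev
                continue
            frame_targets = {
                name: targets[i, k]
                for k, name in enumerate(_MOVING_KP)
                if moving_w[i, k] > 0
            }
            frame_w = {
                name: moving_w[i, k]
                for k, name in enumerate(_MOVING_KP)
                if moving_w[i, k] > 0
            }
            trace: list = []
            q_start = q_prev if settings.warm_start else q_neutral.copy()
            q, cost, it = _solve_frame(
                fitted, frame_targets, frame_w, q_start, q_prev, free_idx, lo, hi,
                settings, trace,
            )
            poses[i] = q
            objectives[i] = cost
            iters[i] = it
            q_prev = q
            cost_traces.append(trace)

    # interpolate unresolved frames from the nearest resolved neighbours
    if unresolved.any():
        ok = ~unresolved
        if not ok.any():
            raise InsufficientDataError("no frame could be resolved")
        t = np.arange(n, dtype=float)
        for j in free_idx:
            poses[unresolved, j] = np.interp(t[unresolved], t[ok], poses[ok, j])

    channels = {
        "shoulder_plane_of_elevation": unwrap_angles(poses[:, 0]),
        "shoulder_angle_of_elevation": poses[:, 1].copy(),
        "shoulder_rotation": unwrap_angles(poses[:, 2]),
        "elbow_flexion": poses[:, 3].copy(),
    }
    if not settings.pronation_locked:
        channels["pronation"] = unwrap_angles(poses[:, 4])
    flag = np.abs(poses[:, 1]) < gimbal_band_deg

    rate = keypoints.rate
    times = keypoints.times
    if target_rate is not None and target_rate != rate:
        channels = {k: resample_scalar(v, rate, target_rate) for k, v in channels.items()}
        r = int(round(target_rate / rate))
        m = (len(times) - 1) * r + 1
        idx = np.clip(np.round(np.arange(m) / r).astype(int), 0, len(flag) - 1)
        flag = flag[idx]
        times = np.arange(m) / target_rate + times[0]
        rate = target_rate

    meta = dict(meta or {})
    meta.setdefault("method", "IK")
    meta["ik_unresolved_frames"] = int(unresolved.sum())
    meta["ik_unresolved_fraction"] = float(unresolved.mean())
    meta["ik_mean_iterations"] = float(iters[~unresolved].mean()) if (~unresolved).any() else 0.0
    meta["ik_max_objective_mm2"] = float(objectives.max(initial=0.0))
    if cost_traces is not None:
        meta["ik_cost_traces"] = cost_traces
    if unresolved.mean() > 0.10:
        meta["trial_warning"] = "more than 10% of frames unresolved"
    return JointAngleTable(
        times=times, rate=rate, channels=channels, meta=meta, gimbal_flag=flag
    )


def compute_reference_angles(
    keypoints: KeypointSeries,
    model: LimbModel,
    settings: IKSettings | None = None,
    filter_spec: FilterSpec | None = None,
    meta: dict | None = None,
) -> JointAngleTable:
    """Reference joint angles: the IK procedure at the native (high) rate,
    with the reference filter settings and no upsampling."""
    if filter_spec is None:
        filter_spec = FilterSpec(order=4, cutoff_hz=8.0, rate_hz=keypoints.rate)
    meta = dict(meta or {})
    meta["method"] = "reference"
    return ik_joint_angles(
        keypoints,
        model,
        settings=settings,
        filter_spec=filter_spec,
        target_rate=None,
        meta=meta,
    )


# ---------------------------------------------------------------------------
# differences
# ---------------------------------------------------------------------------


def align_tables(
    test: JointAngleTable,
    reference: JointAngleTable,
    sync_channel: str | None = None,
    max_lag_s: float = 2.0,
    min_excursion_deg: float = 0.5,
) -> tuple[JointAngleTable, JointAngleTable, int]:
    """Remove the constant inter-system latency by cross-correlating one angle
    channel, then truncate both tables to the common support.

    A single integer lag (at the common rate) is applied to all channels. The
    sync channel is the one with the largest excursion shared by both tables
    (the angle of elevation in most tasks), unless ``sync_channel`` names one
    explicitly. If no channel moves by more than ``min_excursion_deg`` (tasks
    that hold all analysed angles still), the lag is indeterminate and also
    irrelevant; it is set to 0.
    """
    if test.rate != reference.rate:
        raise ParameterError("tables must share a rate before alignment")
    if sync_channel is None:
        shared = [c for c in test.channels if c in reference.channels]
        if not shared:
            raise ParameterError("tables share no channels")
        sync_channel = max(
            shared,
            key=lambda c: min(
                float(np.std(test.channels[c])), float(np.std(reference.channels[c]))
            ),
        )
    excursion = min(
        float(np.std(test.channels[sync_channel])),
        float(np.std(reference.channels[sync_channel])),
    )
    if excursion < min_excursion_deg:
        lag = 0
    else:
        lag, _, _ = cross_correlation_align(
            reference.channels[sync_channel],
            test.channels[sync_channel],
            rate_hz=test.rate,
            max_lag_s=max_lag_s,
        )
    n = min(len(test), len(reference))
    if lag >= 0:
        t_al = test.slice(lag, n)
        r_al = reference.slice(0, n - lag)
    else:
        t_al = test.slice(0, n + lag)
        r_al = reference.slice(-lag, n)
    return t_al, r_al, lag


def build_difference_sets(
    test: JointAngleTable,
    reference: JointAngleTable,
    channels: tuple[str, ...] = ANGLE_CHANNELS,
) -> dict[str, np.ndarray]:
    """Per-frame angle differences (test - reference, deg) per channel.

    Tables must already be sync-aligned and share a rate; frames flagged
    gimbal-degenerate in either table are excluded.
    """
    if test.rate != reference.rate:
        raise ParameterError("tables must share a rate")
    n = min(len(test), len(reference))
    if n == 0:
        raise ParameterError("tables have no overlapping support")
    keep = ~(test.gimbal_flag[:n] | reference.gimbal_flag[:n])
    out = {}
    for ch in channels:
        d = test.channels[ch][:n] - reference.channels[ch][:n]
        out[ch] = d[keep]
    return out
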