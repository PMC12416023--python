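"""Ground-truth movement scripts and simulation of the two measurement systems.

Ten scripted unilateral right-arm movements are generated: five planar
(physiological) tasks that isolate one degree of freedom and five
activity-of-daily-living (ADL) tasks built from smooth multi-joint waypoint
trajectories. Each script repeats its cycle (default 4 s, a deliberately slow
pace) three times and starts/ends at a common seated start posture with the
arm hanging slightly away from the torso.

Two channels are simulated from a script and a limb model:

* a 120 Hz low-noise **reference** channel (optical marker quality), and
* a 30 Hz **markerless** channel with additive keypoint noise (optionally
  anisotropic along the camera depth axis), small random orientation
  perturbations, a constant acquisition latency, fixed per-segment
  device-convention frame offsets, and occasional keypoint misdetections
  (flagged invalid and grossly displaced).

The noise magnitudes are configurable study conditions, not estimates fitted
to any particular device.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.spatial.transform import Rotation

from .errors import ParameterError
from .limb_model import (
    DOF_NAMES,
    KEYPOINT_NAMES,
    SEGMENT_NAMES,
    LimbModel,
    forward_kinematics_batch,
)
from .series import ALL_CHANNELS, JointAngleTable, KeypointSeries, OrientationSeries

__all__ = [
    "MovementScript",
    "NoiseSpec",
    "MOVEMENT_NAMES",
    "PLANAR_TASKS",
    "ADL_TASKS",
    "generate_movement",
    "simulate_reference",
    "simulate_markerless",
]

PLANAR_TASKS = (
    "shoulder_abduction",
    "shoulder_flexion",
    "elbow_flexion",
    "shoulder_rotation",
    "pronation_supination",
)
ADL_TASKS = (
    "brush_hair",
    "perineal_care",
    "collect_change",
    "drink_from_cup",
    "eat_with_spoon",
)
MOVEMENT_NAMES = PLANAR_TASKS + ADL_TASKS

# seated start posture (deg): arm hanging slightly abducted, elbow slightly
# bent, so every trajectory stays strictly inside the joint limits and off the
# shoulder gimbal band
START_POSE = {
    "shoulder_plane": 0.0,
    "shoulder_elev": 10.0,
    "shoulder_rot": 0.0,
    "elbow_flex": 5.0,
    "pronation": 0.0,
}


@dataclass
class MovementScript:
    """Deterministic per-DOF angle trajectories for one scripted task."""

    name: str
    cycle_duration: float
    repetitions: int
    trajectories: dict  # dof name -> callable(phase in [0, 1]) -> deg
    placement: str | None = None

    def __post_init__(self):
        if self.repetitions < 1:
            raise ParameterError("repetitions must be >= 1")
        if self.cycle_duration <= 0:
            raise ParameterError("cycle_duration must be positive")

    @property
    def duration(self) -> float:
        return self.cycle_duration * self.repetitions

    def sample(self, times) -> np.ndarray:
        """Evaluate the pose (deg, DOF_NAMES order) at the given times (s).

        Times are clamped to [0, duration]; the cycle repeats periodically.
        """
        t = np.clip(np.asarray(times, dtype=float), 0.0, self.duration)
        phase = (t / self.cycle_duration) % 1.0
        phase[t >= self.duration] = 1.0
        out = np.empty((len(t), len(DOF_NAMES)))
        for i, dof in enumerate(DOF_NAMES):
            out[:, i] = self.trajectories[dof](phase)
        return out


def _const(v: float):
    return lambda ph: np.full_like(np.asarray(ph, dtype=float), v)


def _bump(base: float, peak: float):
    """Raised-cosine excursion base -> peak -> base over one cycle (C1)."""
    amp = peak - base
    return lambda ph: base + amp * 0.5 * (1.0 - np.cos(2.0 * np.pi * np.asarray(ph)))


def _sine(base: float, amp: float):
    """Symmetric two-sided excursion base -> base-amp -> base -> base+amp -> base."""
    return lambda ph: base - amp * np.sin(2.0 * np.pi * np.asarray(ph))


def _waypoints(points: list[tuple[float, float]]):
    """Monotone (overshoot-free) C1 interpolant through (phase, value) pairs.

    Flat anchors are inserted near the cycle ends so repetitions join with
    near-zero velocity.
    """
    phases = [p for p, _ in points]
    values = [v for _, v in points]
    if phases[0] != 0.0 or phases[-1] != 1.0:
        raise ParameterError("waypoints must span phases 0 to 1")
    if values[0] != values[-1]:
        raise ParameterError("cycle must start and end at the same value")
    ph = [0.0, 0.03] + phases[1:-1] + [0.97, 1.0]
    va = [values[0], values[0]] + values[1:-1] + [values[-1], values[-1]]
    interp = PchipInterpolator(ph, va)
    return lambda p: interp(np.asarray(p, dtype=float))


def _smoothstep(ph, lo, hi, v0, v1):
    """C1 transition from v0 to v1 as phase goes lo -> hi, constant outside."""
    ph = np.asarray(ph, dtype=float)
    s = np.clip((ph - lo) / (hi - lo), 0.0, 1.0)
    return v0 + (v1 - v0) * (3.0 * s**2 - 2.0 * s**3)


def _shoulder_flexion_traj(peak_fwd: float, peak_back: float):
    """Forward elevation at plane +90, then backward extension at plane -85.

    The plane channel sweeps between the two half-planes while the arm is at
    its low start elevation, keeping the keypoint paths continuous.
    """
    base = START_POSE["shoulder_elev"]

    def plane(ph):
        ph = np.asarray(ph, dtype=float)
        up = _smoothstep(ph, 0.0, 0.10, 0.0, 90.0)
        mid = _smoothstep(ph, 0.42, 0.58, 0.0, -175.0)
        down = _smoothstep(ph, 0.90, 1.0, 0.0, 85.0)
        return up + mid + down

    def elev(ph):
        ph = np.asarray(ph, dtype=float)
        out = np.full_like(ph, base)
        m1 = (ph >= 0.10) & (ph <= 0.42)
        s1 = (ph[m1] - 0.10) / 0.32
        out[m1] = base + (peak_fwd - base) * 0.5 * (1.0 - np.cos(2.0 * np.pi * s1))
        m2 = (ph >= 0.58) & (ph <= 0.90)
        s2 = (ph[m2] - 0.58) / 0.32
        out[m2] = base + (peak_back - base) * 0.5 * (1.0 - np.cos(2.0 * np.pi * s2))
        return out

    return plane, elev


def generate_movement(
    name: str,
    cycle_duration: float = 4.0,
    repetitions: int = 3,
    peak_params: dict | None = None,
) -> MovementScript:
    """Build the deterministic angle script for one of the ten tasks.

    ``peak_params`` overrides the documented default peak amplitudes (deg) of
    the planar tasks (keys: ``peak``, and for two-sided tasks ``peak_back``).
    """
    if name not in MOVEMENT_NAMES:
        raise ParameterError(f"unknown movement {name!r}; expected one of {MOVEMENT_NAMES}")
    pk = dict(peak_params or {})
    sp = START_POSE
    tr: dict = {dof: _const(v) for dof, v in sp.items()}
    if name == "shoulder_flexion":
        # forward raise plus backward extension: two movements in one cycle
        cycle_duration = 2.0 * cycle_duration

    if name == "shoulder_abduction":
        tr["shoulder_elev"] = _bump(sp["shoulder_elev"], pk.get("peak", 150.0))
    elif name == "shoulder_flexion":
        plane, elev = _shoulder_flexion_traj(pk.get("peak", 150.0), pk.get("peak_back", 40.0))
        tr["shoulder_plane"] = plane
        tr["shoulder_elev"] = elev
    elif name == "elbow_flexion":
        tr["elbow_flex"] = _bump(sp["elbow_flex"], pk.get("peak", 130.0))
    elif name == "shoulder_rotation":
        tr["elbow_flex"] = _const(90.0)
        tr["shoulder_rot"] = _sine(0.0, pk.get("peak", 60.0))
    elif name == "pronation_supination":
        tr["elbow_flex"] = _const(90.0)
        tr["pronation"] = _sine(0.0, pk.get("peak", 80.0))
    elif name == "brush_hair":
        tr["shoulder_plane"] = _waypoints(
            [(0, 0), (0.2, 70), (0.5, 80), (0.8, 70), (1, 0)]
        )
        tr["shoulder_elev"] = _waypoints(
            [(0, 10), (0.2, 60), (0.35, 105), (0.5, 115), (0.65, 105), (0.8, 55), (1, 10)]
        )
        tr["shoulder_rot"] = _waypoints(
            [(0, 0), (0.3, -30), (0.5, -45), (0.7, -30), (1, 0)]
        )
        tr["elbow_flex"] = _waypoints(
            [(0, 5), (0.2, 40), (0.35, 105), (0.5, 85), (0.65, 110), (0.8, 40), (1, 5)]
        )
        tr["pronation"] = _waypoints([(0, 0), (0.4, -40), (0.6, -40), (1, 0)])
    elif name == "perineal_care":
        tr["shoulder_plane"] = _waypoints([(0, 0), (0.35, -60), (0.65, -60), (1, 0)])
        tr["shoulder_elev"] = _waypoints(
            [(0, 10), (0.35, 35), (0.5, 40), (0.65, 35), (1, 10)]
        )
        tr["shoulder_rot"] = _waypoints([(0, 0), (0.4, -55), (0.6, -55), (1, 0)])
        tr["elbow_flex"] = _waypoints([(0, 5), (0.35, 65), (0.5, 70), (0.65, 65), (1, 5)])
        tr["pronation"] = _waypoints([(0, 0), (0.45, 30), (0.55, 30), (1, 0)])
    elif name == "collect_change":
        tr["shoulder_plane"] = _waypoints(
            [(0, 0), (0.25, 70), (0.45, 70), (0.7, 20), (1, 0)]
        )
        tr["shoulder_elev"] = _waypoints(
            [(0, 10), (0.25, 55), (0.45, 60), (0.7, 25), (1, 10)]
        )
        tr["shoulder_rot"] = _waypoints(
            [(0, 0), (0.3, -20), (0.5, -25), (0.75, -10), (1, 0)]
        )
        tr["elbow_flex"] = _waypoints(
            [(0, 5), (0.25, 35), (0.45, 45), (0.7, 70), (1, 5)]
        )
        tr["pronation"] = _waypoints(
            [(0, 0), (0.35, -50), (0.5, -60), (0.75, 0), (1, 0)]
        )
    elif name == "drink_from_cup":
        tr["shoulder_plane"] = _waypoints(
            [(0, 0), (0.25, 75), (0.5, 80), (0.75, 75), (1, 0)]
        )
        tr["shoulder_elev"] = _waypoints(
            [(0, 10), (0.25, 50), (0.5, 55), (0.75, 50), (1, 10)]
        )
        tr["shoulder_rot"] = _waypoints([(0, 0), (0.4, -20), (0.6, -20), (1, 0)])
        tr["elbow_flex"] = _waypoints(
            [(0, 5), (0.25, 45), (0.5, 120), (0.75, 45), (1, 5)]
        )
        tr["pronation"] = _waypoints([(0, 0), (0.4, -30), (0.6, -30), (1, 0)])
    elif name == "eat_with_spoon":
        tr["shoulder_plane"] = _waypoints(
            [(0, 0), (0.3, 70), (0.5, 75), (0.7, 70), (1, 0)]
        )
        tr["shoulder_elev"] = _waypoints(
            [(0, 10), (0.3, 45), (0.5, 50), (0.7, 45), (1, 10)]
        )
        tr["shoulder_rot"] = _waypoints([(0, 0), (0.5, -25), (1, 0)])
        tr["elbow_flex"] = _waypoints(
            [(0, 5), (0.3, 50), (0.45, 125), (0.55, 125), (0.7, 50), (1, 5)]
        )
        tr["pronation"] = _waypoints([(0, 0), (0.45, -45), (0.55, -45), (1, 0)])

    return MovementScript(
        name=name,
        cycle_duration=cycle_duration,
        repetitions=repetitions,
        trajectories=tr,
    )


def task_type(name: str) -> str:
    if name in PLANAR_TASKS:
        return "Planar"
    if name in ADL_TASKS:
        return "ADL"
    raise ParameterError(f"unknown movement {name!r}")


# ---------------------------------------------------------------------------
# measurement simulation
# ---------------------------------------------------------------------------

_IDENTITY_QUAT = (1.0, 0.0, 0.0, 0.0)


@dataclass(frozen=True)
class NoiseSpec:
    """Error structure of one simulated measurement channel.

    ``frame_offsets`` are constant per-segment rotations (quaternions,
    scalar-first) that emulate a device whose segment-frame conventions differ
    from the anatomical ones; the angle pipeline removes them with the matching
    realignment. ``depth_axis``/``depth_multiplier`` inflate keypoint noise
    along the camera viewing axis to emulate depth estimation error.
    """

    keypoint_sd_mm: float = 0.0
    orientation_sd_deg: float = 0.0
    latency_s: float = 0.0
    misdetection_prob: float = 0.0
    misdetection_sd_mm: float = 100.0
    frame_offsets: dict = field(default_factory=dict)  # segment -> quat wxyz
    depth_axis: tuple[float, float, float] | None = None
    depth_multiplier: float = 1.0

    def __post_init__(self):
        if min(self.keypoint_sd_mm, self.orientation_sd_deg, self.misdetection_sd_mm) < 0:
            raise ParameterError("noise standard deviations must be >= 0")
        if not 0.0 <= self.misdetection_prob <= 1.0:
            raise ParameterError("misdetection_prob must be in [0, 1]")

    def scaled(self, factor: float) -> "NoiseSpec":
        """Scale the stochastic error magnitudes (latency and frame offsets,
        which are systematic, are kept)."""
        return replace(
            self,
            keypoint_sd_mm=self.keypoint_sd_mm * factor,
            orientation_sd_deg=self.orientation_sd_deg * factor,
            misdetection_prob=self.misdetection_prob * (factor > 0),
        )


def _sample_truth(script: MovementScript, rate: float, latency: float = 0.0):
    n = int(round(script.duration * rate)) + 1
    times = np.arange(n) / rate
    poses = script.sample(times - latency)
    return times, poses


def _truth_table(times, poses, rate, script) -> JointAngleTable:
    channels = {ch: poses[:, i].copy() for i, ch in enumerate(ALL_CHANNELS)}
    return JointAngleTable(
        times=times,
        rate=rate,
        channels=channels,
        meta={"method": "truth", "movement": script.name},
    )


def _apply_keypoint_noise(points, noise: NoiseSpec, rng: np.random.Generator):
    if noise.keypoint_sd_mm <= 0:
        return points.copy()
    g = rng.normal(0.0, noise.keypoint_sd_mm, size=points.shape)
    if noise.depth_axis is not None and noise.depth_multiplier != 1.0:
        d = np.asarray(noise.depth_axis, dtype=float)
        d = d / np.linalg.norm(d)
        along = g @ d
        g = g + (noise.depth_multiplier - 1.0) * along[..., None] * d
    return points + g


def _apply_orientation_noise(quats, sd_deg: float, rng: np.random.Generator):
    """Perturb each quaternion by a small random rotation (rotvec with i.i.d.
    normal components of the given sd per axis) and renormalise."""
    if sd_deg <= 0:
        return quats.copy()
    n, s, _ = quats.shape
    rotvecs = rng.normal(0.0, np.radians(sd_deg), size=(n * s, 3))
    noise_rots = Rotation.from_rotvec(rotvecs)
    base = Rotation.from_quat(quats.reshape(-1, 4), scalar_first=True)
    out = (noise_rots * base).as_quat(scalar_first=True)
    out[out[:, 0] < 0] *= -1.0
    return out.reshape(n, s, 4)


def simulate_reference(
    script: MovementScript,
    model: LimbModel,
    rate: float = 120.0,
    noise: NoiseSpec | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[KeypointSeries, OrientationSeries, JointAngleTable]:
    """Simulate the high-rate reference channel plus the ground-truth table.

    With a zero noise spec the keypoints equal the forward kinematics of the
    script exactly.
    """
    noise = noise or NoiseSpec()
    rng = rng or np.random.default_rng(0)
    times, poses = _sample_truth(script, rate, latency=noise.latency_s)
    points, quats = forward_kinematics_batch(model, poses, check_limits=False)
    points = _apply_keypoint_noise(points, noise, rng)
    quats = _apply_orientation_noise(quats, noise.orientation_sd_deg, rng)
    valid = np.ones(points.shape[:2], dtype=bool)
    kp = KeypointSeries(times=times, names=KEYPOINT_NAMES, points=points, valid=valid, rate=rate)
    ors = OrientationSeries(times=times, segments=SEGMENT_NAMES, quats=quats, rate=rate)
    truth_times, truth_poses = _sample_truth(script, rate)
    return kp, ors, _truth_table(truth_times, truth_poses, rate, script)


def simulate_markerless(
    script: MovementScript,
    model: LimbModel,
    rate: float = 30.0,
    noise: NoiseSpec | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[KeypointSeries, OrientationSeries]:
    """Simulate the low-rate markerless channel.

    A sample with timestamp ``t`` reports the body state at ``t - latency``
    (constant acquisition delay). Per-segment constant device-convention
    rotations post-multiply the true orientations; misdetected keypoints are
    flagged invalid and grossly displaced.
    """
    noise = noise or NoiseSpec()
    rng = rng or np.random.default_rng(0)
    times, poses = _sample_truth(script, rate, latency=noise.latency_s)
    points, quats = forward_kinematics_batch(model, poses, check_limits=False)

    # device-convention frame offsets: R_device = R_true @ R_offset
    if noise.frame_offsets:
        for j, seg in enumerate(SEGMENT_NAMES):
            q_off = noise.frame_offsets.get(seg, _IDENTITY_QUAT)
            r_off = Rotation.from_quat(np.asarray(q_off, float), scalar_first=True)
            base = Rotation.from_quat(quats[:, j], scalar_first=True)
            out = (base * r_off).as_quat(scalar_first=True)
            out[out[:, 0] < 0] *= -1.0
            quats[:, j] = out

    points = _apply_keypoint_noise(points, noise, rng)
    quats = _apply_orientation_noise(quats, noise.orientation_sd_deg, rng)

    valid = np.ones(points.shape[:2], dtype=bool)
    if noise.misdetection_prob > 0:
        miss = rng.random(points.shape[:2]) < noise.misdetection_prob
        valid &= ~miss
        points[miss] += rng.normal(0.0, noise.misdetection_sd_mm, size=(int(miss.sum()), 3))

    kp = KeypointSeries(times=times, names=KEYPOINT_NAMES, points=points, valid=valid, rate=rate)
    ors = OrientationSeries(times=times, segments=SEGMENT_NAMES, quats=quats, rate=rate)
    return kp, ors
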