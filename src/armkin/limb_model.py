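"""Kinematic chain of the upper limb.

The model is a deliberately reduced upper-limb skeleton: a fixed thorax, a
rigid clavicle offset to the glenohumeral centre, a 3-DOF ball shoulder whose
generalised coordinates *are* the intrinsic Y-X-Y angles (plane of elevation,
angle of elevation, axial rotation), a 1-DOF elbow flexion hinge (axis fixed
along the humerus Z axis) and a 1-DOF, lockable forearm pronation hinge about
the forearm long axis. Shoulder-girdle (clavicle/scapula) motion is absorbed
into the ball joint because single-camera keypoints carry no scapular
information.

Frame conventions
-----------------
The thorax frame is the world frame: +Y up, X posterior (so the subject faces
-X), and the subject's right side along -Z (right-handed anatomical triad:
right = anterior x up). At the neutral pose all segment frames coincide and
the arm hangs along -Y. Positive plane of elevation moves the raised arm from
the lateral (abduction) plane at 0 deg toward the forward-flexion plane at
+90 deg. Lengths are mm, angles degrees.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import InsufficientDataError, JointLimitError, ParameterError
from .series import KeypointSeries

__all__ = [
    "DOF_NAMES",
    "KEYPOINT_NAMES",
    "SEGMENT_NAMES",
    "LimbModel",
    "default_model",
    "forward_kinematics",
    "forward_kinematics_batch",
    "scale_model_from_keypoints",
    "axis_independence_test",
]

DOF_NAMES = ("shoulder_plane", "shoulder_elev", "shoulder_rot", "elbow_flex", "pronation")
KEYPOINT_NAMES = ("sternum", "c7", "shoulder", "elbow", "wrist", "hand")
SEGMENT_NAMES = ("thorax", "humerus", "forearm")

DEFAULT_LIMITS = {
    "shoulder_plane": (-90.0, 130.0),
    "shoulder_elev": (0.0, 180.0),
    "shoulder_rot": (-90.0, 90.0),
    "elbow_flex": (0.0, 150.0),
    "pronation": (-90.0, 90.0),
}


@dataclass(frozen=True)
class LimbModel:
    """Segment dimensions (mm), joint limits (deg) and locked DOFs."""

    thorax_height: float
    clavicle_offset: tuple[float, float, float]
    humerus_length: float
    forearm_length: float
    hand_offset: tuple[float, float, float]
    sternum_offset: tuple[float, float, float]
    c7_offset: tuple[float, float, float]
    limits: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_LIMITS)
    )
    locked: frozenset[str] = frozenset()

    def __post_init__(self):
        for name in ("thorax_height", "humerus_length", "forearm_length"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        for dof, (lo, hi) in self.limits.items():
            if dof not in DOF_NAMES:
                raise ParameterError(f"unknown DOF {dof!r}")
            if lo >= hi:
                raise ParameterError(f"limit_lo >= limit_hi for {dof!r}")
        unknown = set(self.locked) - set(DOF_NAMES)
        if unknown:
            raise ParameterError(f"unknown locked DOFs {sorted(unknown)}")

    @property
    def free_dofs(self) -> tuple[str, ...]:
        return tuple(d for d in DOF_NAMES if d not in self.locked)

    def check_pose(self, pose) -> np.ndarray:
        pose = np.asarray(pose, dtype=float)
        if pose.shape != (len(DOF_NAMES),):
            raise ParameterError(f"pose must have {len(DOF_NAMES)} coordinates")
        for i, dof in enumerate(DOF_NAMES):
            lo, hi = self.limits[dof]
            if not (lo - 1e-9 <= pose[i] <= hi + 1e-9):
                raise JointLimitError(
                    f"{dof} = {pose[i]:.3f} deg outside limits [{lo}, {hi}]"
                )
        return pose

    def with_lock(self, dof: str, locked: bool = True) -> "LimbModel":
        s = set(self.locked)
        (s.add if locked else s.discard)(dof)
        return dataclasses.replace(self, locked=frozenset(s))

    # -- plain-text config serialization (key: value) -----------------------
    def to_config(self) -> str:
        lines = [
            "# armkin limb model (lengths mm, limits deg)",
            f"thorax_height: {self.thorax_height!r}",
            f"clavicle_offset: {list(self.clavicle_offset)!r}",
            f"humerus_length: {self.humerus_length!r}",
            f"forearm_length: {self.forearm_length!r}",
            f"hand_offset: {list(self.hand_offset)!r}",
            f"sternum_offset: {list(self.sternum_offset)!r}",
            f"c7_offset: {list(self.c7_offset)!r}",
        ]
        for dof in DOF_NAMES:
            lo, hi = self.limits[dof]
            lines.append(f"limit_{dof}: [{lo!r}, {hi!r}]")
        lines.append(f"locked: {sorted(self.locked)!r}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_config(cls, text: str) -> "LimbModel":
        import ast

        raw: dict[str, object] = {}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, val = line.partition(":")
            raw[key.strip()] = ast.literal_eval(val.strip())
        limits = {
            dof: tuple(raw.pop(f"limit_{dof}")) for dof in DOF_NAMES if f"limit_{dof}" in raw
        }
        locked = frozenset(raw.pop("locked", []))
        return cls(
            thorax_height=float(raw["thorax_height"]),
            clavicle_offset=tuple(raw["clavicle_offset"]),
            humerus_length=float(raw["humerus_length"]),
            forearm_length=float(raw["forearm_length"]),
            hand_offset=tuple(raw["hand_offset"]),
            sternum_offset=tuple(raw["sternum_offset"]),
            c7_offset=tuple(raw["c7_offset"]),
            limits=limits or dict(DEFAULT_LIMITS),
            locked=locked,
        )


def default_model(participant_scale: float = 1.0) -> LimbModel:
    """Reference anthropometry scaled uniformly by ``participant_scale``.

    At scale 1 the humerus is 300 mm and the forearm 260 mm; realistic adult
    participants fall in roughly [0.8, 1.2].
    """
    s = float(participant_scale)
    if s <= 0:
        raise ParameterError("participant_scale must be positive")
    return LimbModel(
        thorax_height=480.0 * s,
        clavicle_offset=(0.0, -20.0 * s, -180.0 * s),
        humerus_length=300.0 * s,
        forearm_length=260.0 * s,
        hand_offset=(-60.0 * s, -60.0 * s, 0.0),
        sternum_offset=(-80.0 * s, -144.0 * s, 0.0),
        c7_offset=(60.0 * s, 0.0, 0.0),
    )


def _rot_y(a: float) -> np.ndarray:
    c, s = math.cos(a), math.sin(a)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def _rot_x(a: float) -> np.ndarray:
    c, s = math.cos(a), math.sin(a)
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def _rot_z(a: float) -> np.ndarray:
    c, s = math.cos(a), math.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def segment_rotations(pose_deg) -> tuple[np.ndarray, np.ndarray]:
    """World rotations of the humerus and forearm for one pose (degrees)."""
    p, e, r, f, pr = np.radians(np.asarray(pose_deg, dtype=float))
    R_h = _rot_y(p) @ _rot_x(e) @ _rot_y(r)
    cf, sf = math.cos(f), math.sin(f)
    cp, sp = math.cos(pr), math.sin(pr)
    Rz = np.array([[cf, -sf, 0.0], [sf, cf, 0.0], [0.0, 0.0, 1.0]])
    Ry = np.array([[cp, 0.0, sp], [0.0, 1.0, 0.0], [-sp, 0.0, cp]])
    R_f = R_h @ Rz @ Ry
    return R_h, R_f


def forward_kinematics(
    model: LimbModel, pose_deg, check_limits: bool = True
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Keypoint positions (mm) and segment orientations for a single pose.

    Returns ``(keypoints, orientations)`` where orientations are canonical
    unit quaternions ``[w, x, y, z]`` per segment.
    """
    pose = np.asarray(pose_deg, dtype=float)
    if check_limits:
        model.check_pose(pose)
    R_h, R_f = segment_rotations(pose)
    shoulder = np.asarray(model.clavicle_offset, dtype=float)
    elbow = shoulder + R_h @ np.array([0.0, -model.humerus_length, 0.0])
    wrist = elbow + R_f @ np.array([0.0, -model.forearm_length, 0.0])
    hand = wrist + R_f @ np.asarray(model.hand_offset, dtype=float)
    keypoints = {
        "sternum": np.asarray(model.sternum_offset, dtype=float),
        "c7": np.asarray(model.c7_offset, dtype=float),
        "shoulder": shoulder,
        "elbow": elbow,
        "wrist": wrist,
        "hand": hand,
    }
    quats = Rotation.from_matrix(np.stack([np.eye(3), R_h, R_f])).as_quat(
        scalar_first=True
    )
    quats[quats[:, 0] < 0] *= -1.0
    orientations = dict(zip(SEGMENT_NAMES, quats))
    return keypoints, orientations


def forward_kinematics_batch(
    model: LimbModel, poses_deg: np.ndarray, check_limits: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised FK over poses ``(n, 5)`` deg.

    Returns ``(points (n, 6, 3) mm in KEYPOINT_NAMES order,
    quats (n, 3, 4) in SEGMENT_NAMES order)``.
    """
    poses = np.asarray(poses_deg, dtype=float)
    if poses.ndim != 2 or poses.shape[1] != len(DOF_NAMES):
        raise ParameterError("poses must have shape (n, 5)")
    if check_limits:
        for i, dof in enumerate(DOF_NAMES):
            lo, hi = model.limits[dof]
            bad = (poses[:, i] < lo - 1e-9) | (poses[:, i] > hi + 1e-9)
            if np.any(bad):
                j = int(np.argmax(bad))
                raise JointLimitError(
                    f"{dof} = {poses[j, i]:.3f} deg outside limits [{lo}, {hi}] "
                    f"at frame {j}"
                )
    n = len(poses)
    rad = np.radians(poses)
    R_sh = Rotation.from_euler("YXY", rad[:, :3]).as_matrix()
    R_el = Rotation.from_euler("ZY", rad[:, 3:5]).as_matrix()
    R_fo = np.einsum("nij,njk->nik", R_sh, R_el)
    shoulder = np.broadcast_to(np.asarray(model.clavicle_offset, float), (n, 3))
    elbow = shoulder + R_sh @ np.array([0.0, -model.humerus_length, 0.0])
    wrist = elbow + R_fo @ np.array([0.0, -model.forearm_length, 0.0])
    hand = wrist + R_fo @ np.asarray(model.hand_offset, dtype=float)
    points = np.empty((n, len(KEYPOINT_NAMES), 3))
    points[:, 0] = np.asarray(model.sternum_offset, dtype=float)
    points[:, 1] = np.asarray(model.c7_offset, dtype=float)
    points[:, 2] = shoulder
    points[:, 3] = elbow
    points[:, 4] = wrist
    points[:, 5] = hand
    quats = np.empty((n, len(SEGMENT_NAMES), 4))
    quats[:, 0] = [1.0, 0.0, 0.0, 0.0]
    quats[:, 1] = Rotation.from_matrix(R_sh).as_quat(scalar_first=True)
    quats[:, 2] = Rotation.from_matrix(R_fo).as_quat(scalar_first=True)
    neg = quats[:, :, 0] < 0
    quats[neg] *= -1.0
    return points, quats


def scale_model_from_keypoints(
    template: LimbModel, keypoints: KeypointSeries, min_frames: int = 30
) -> LimbModel:
    """Scale the template so segment lengths match observed keypoint distances.

    Humerus and forearm lengths become the medians over valid frames of the
    shoulder-elbow and elbow-wrist distances; the remaining dimensions are
    scaled by the mean of the two length ratios.
    """
    i_s, i_e, i_w = (keypoints.index(n) for n in ("shoulder", "elbow", "wrist"))
    ok_h = keypoints.valid[:, i_s] & keypoints.valid[:, i_e]
    ok_f = keypoints.valid[:, i_e] & keypoints.valid[:, i_w]
    if int(ok_h.sum()) < min_frames or int(ok_f.sum()) < min_frames:
        raise InsufficientDataError(
            f"need at least {min_frames} valid frames to scale the model"
        )
    pts = keypoints.points
    hum = float(np.median(np.linalg.norm(pts[ok_h, i_e] - pts[ok_h, i_s], axis=1)))
    fore = float(np.median(np.linalg.norm(pts[ok_f, i_w] - pts[ok_f, i_e], axis=1)))
    ratio = 0.5 * (hum / template.humerus_length + fore / template.forearm_length)
    scale3 = lambda v: tuple(ratio * x for x in v)  # noqa: E731
    return dataclasses.replace(
        template,
        humerus_length=hum,
        forearm_length=fore,
        thorax_height=ratio * template.thorax_height,
        clavicle_offset=scale3(template.clavicle_offset),
        hand_offset=scale3(template.hand_offset),
        sternum_offset=scale3(template.sternum_offset),
        c7_offset=scale3(template.c7_offset),
    )


def joint_axes_world(pose_deg) -> dict[str, np.ndarray]:
    """World-frame unit vectors of the six Euler rotation axes at a pose.

    The six axes are the instantaneous axes of the two joint decompositions
    used by the coordinate-frame method: shoulder Y-X-Y (plane of elevation,
    elevation, axial rotation) and elbow Z-X-Y (flexion, carrying line of
    nodes, pronation about the forearm long axis).
    """
    p, e, r, f, _ = np.radians(np.asarray(pose_deg, dtype=float))
    ex = np.array([1.0, 0.0, 0.0])
    ey = np.array([0.0, 1.0, 0.0])
    ez = np.array([0.0, 0.0, 1.0])
    Ry_p = _rot_y(p)
    R_h = Ry_p @ _rot_x(e) @ _rot_y(r)
    cf, sf = math.cos(f), math.sin(f)
    Rz_f = np.array([[cf, -sf, 0.0], [sf, cf, 0.0], [0.0, 0.0, 1.0]])
    return {
        "shoulder_plane": ey,
        "shoulder_elev": Ry_p @ ex,
        "shoulder_rot": R_h @ ey,
        "elbow_flexion": R_h @ ez,
        "elbow_carrying": R_h @ Rz_f @ ex,
        "pronation": R_h @ Rz_f @ ey,
    }


def axis_independence_test(model: LimbModel, pose_deg, tol: float = 1e-3) -> dict:
    """Dot-product diagnostic for degenerate joint axes at a pose.

    An axis counts as independent when ``|dot|`` with every earlier axis stays
    below ``1 - tol``. With the forearm aligned to the humerus (elbow
    extended) the pronation axis coincides with the shoulder axial-rotation
    axis and only five of the six axes are independent.

    Returns a report with the axis names, all pairwise ``|dot|`` values and
    the independent-axis count.
    """
    model.check_pose(pose_deg)
    axes = joint_axes_world(pose_deg)
    names = list(axes)
    vecs = [axes[n] / np.linalg.norm(axes[n]) for n in names]
    pair_dots = {}
    independent = 0
    for i, n in enumerate(names):
        indep = True
        for j in range(i):
            d = abs(float(np.dot(vecs[i], vecs[j])))
            pair_dots[(names[j], n)] = d
            if d >= 1.0 - tol:
                indep = False
        independent += indep
    return {"axes": names, "abs_dots": pair_dots, "independent_count": independent}
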