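"""Orientation algebra: quaternions, rotation matrices, SLERP, intrinsic Euler
angles with deterministic gimbal handling, angle unwrapping, and estimation of
a fixed centre of rotation from rigid-marker trajectories.

Conventions (used throughout the package):

* Quaternions are stored ``[w, x, y, z]`` (scalar first) and represent
  **active** rotations in right-handed frames.
* ``q`` and ``-q`` encode the same rotation; functions canonicalise outputs to
  ``w >= 0``.
* Euler sequences are **intrinsic** (each rotation about the frame produced by
  the previous one), written e.g. ``"YXY"`` or ``"ZXY"``. Angles are degrees.
* At a gimbal-degenerate orientation the decomposition sets the third angle to
  zero, puts the whole free rotation in the first angle, and flags the sample.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import (
    InvalidOrientationError,
    ParameterError,
    RankDeficiencyError,
)

__all__ = [
    "quat_to_matrix",
    "matrix_to_quat",
    "quat_multiply",
    "canonicalize",
    "rotation_angle_deg",
    "slerp",
    "slerp_smooth",
    "compose_euler",
    "euler_intrinsic",
    "unwrap_angles",
    "estimate_rotation_center",
]

_VALID_AXES = set("XYZ")


def _check_sequence(seq: str) -> str:
    seq = seq.upper()
    if len(seq) != 3 or any(a not in _VALID_AXES for a in seq):
        raise ParameterError(f"Euler sequence must be 3 axes from X/Y/Z, got {seq!r}")
    if seq[0] == seq[1] or seq[1] == seq[2]:
        raise ParameterError(f"consecutive Euler axes must differ, got {seq!r}")
    return seq


def _as_unit_quat(q, tol: float = 1e-6) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    if q.shape != (4,):
        raise InvalidOrientationError(f"quaternion must have shape (4,), got {q.shape}")
    if not np.all(np.isfinite(q)):
        raise InvalidOrientationError("quaternion has non-finite components")
    n = float(np.linalg.norm(q))
    if n < 1e-12:
        raise InvalidOrientationError("quaternion has zero norm")
    if abs(n - 1.0) > tol:
        raise InvalidOrientationError(f"quaternion norm {n:.3g} is not 1 within {tol:g}")
    return q / n


def canonicalize(q) -> np.ndarray:
    """Return the sign-canonical unit quaternion (``w >= 0``) equal to ``q``."""
    q = _as_unit_quat(q)
    if q[0] < 0 or (q[0] == 0 and (q[np.nonzero(q)[0][0]] < 0)):
        q = -q
    return q


def quat_to_matrix(q) -> np.ndarray:
    """Convert a unit quaternion ``[w, x, y, z]`` to a 3x3 rotation matrix."""
    q = _as_unit_quat(q)
    return Rotation.from_quat(q, scalar_first=True).as_matrix()


def _check_matrix(R, tol: float = 1e-6) -> np.ndarray:
    R = np.asarray(R, dtype=float)
    if R.shape != (3, 3) or not np.all(np.isfinite(R)):
        raise InvalidOrientationError("rotation matrix must be a finite 3x3 array")
    if not np.allclose(R.T @ R, np.eye(3), atol=tol):
        raise InvalidOrientationError("matrix is not orthonormal")
    if np.linalg.det(R) < 0:
        raise InvalidOrientationError("matrix determinant is negative (reflection)")
    return R


def matrix_to_quat(R) -> np.ndarray:
    """Convert a rotation matrix to the canonical (``w >= 0``) unit quaternion."""
    R = _check_matrix(R)
    q = Rotation.from_matrix(R).as_quat(scalar_first=True)
    return canonicalize(q)


def quat_multiply(qa, qb) -> np.ndarray:
    """Hamilton product ``qa * qb`` (apply ``qb`` first, then ``qa``)."""
    qa = _as_unit_quat(qa)
    qb = _as_unit_quat(qb)
    ra = Rotation.from_quat(qa, scalar_first=True)
    rb = Rotation.from_quat(qb, scalar_first=True)
    return canonicalize((ra * rb).as_quat(scalar_first=True))


def rotation_angle_deg(qa, qb) -> float:
    """Geodesic angle (degrees) between the rotations ``qa`` and ``qb``."""
    qa = _as_unit_quat(qa)
    qb = _as_unit_quat(qb)
    dot = abs(float(np.dot(qa, qb)))
    dot = min(dot, 1.0)
    return float(np.degrees(2.0 * np.arccos(dot)))


def slerp(q0, q1, t: float) -> np.ndarray:
    """Spherical linear interpolation from ``q0`` to ``q1`` along the shortest arc.

    ``t = 0`` returns ``q0`` and ``t = 1`` returns ``q1`` (up to quaternion
    sign: outputs are canonicalised to ``w >= 0``). The rotation angle from
    ``q0`` to the result is ``t`` times the geodesic angle from ``q0`` to
    ``q1``.
    """
    q0 = _as_unit_quat(q0)
    q1 = _as_unit_quat(q1)
    t = float(t)
    if not 0.0 <= t <= 1.0:
        raise ParameterError(f"slerp parameter t must be in [0, 1], got {t}")
    dot = float(np.dot(q0, q1))
    if dot < 0.0:  # shortest arc
        q1 = -q1
        dot = -dot
    dot = min(dot, 1.0)
    theta = np.arccos(dot)
    if theta < 1e-10:  # nearly identical: linear blend is exact to roundoff
        out = (1.0 - t) * q0 + t * q1
    else:
        s = np.sin(theta)
        out = (np.sin((1.0 - t) * theta) / s) * q0 + (np.sin(t * theta) / s) * q1
    return canonicalize(out / np.linalg.norm(out))


def slerp_smooth(series, alpha: float) -> np.ndarray:
    """First-order exponential smoothing on the rotation manifold.

    ``q_hat[t] = slerp(q_hat[t-1], q[t], alpha)``: ``alpha = 1`` returns the
    input unchanged, small ``alpha`` trusts the running estimate more. A
    constant series is a fixed point for any ``alpha``.
    """
    alpha = float(alpha)
    if not 0.0 < alpha <= 1.0:
        raise ParameterError(f"smoothing alpha must be in (0, 1], got {alpha}")
    qs = np.asarray(series, dtype=float)
    if qs.ndim != 2 or qs.shape[1] != 4:
        raise InvalidOrientationError("series must have shape (n, 4)")
    if qs.shape[0] == 0:
        return qs.copy()
    out = np.empty_like(qs)
    out[0] = canonicalize(qs[0])
    if alpha == 1.0:
        for i in range(1, len(qs)):
            out[i] = canonicalize(qs[i])
        return out
    for i in range(1, len(qs)):
        out[i] = slerp(out[i - 1], qs[i], alpha)
    return out


def compose_euler(seq: str, angles_deg) -> np.ndarray:
    """Rotation matrix from intrinsic Euler angles (degrees) in sequence ``seq``."""
    seq = _check_sequence(seq)
    angles = np.asarray(angles_deg, dtype=float)
    return Rotation.from_euler(seq, angles, degrees=True).as_matrix()


def euler_intrinsic(R, seq: str) -> tuple[np.ndarray, bool]:
    """Decompose a rotation matrix into intrinsic Euler angles (degrees).

    Returns ``(angles, degenerate)``. For symmetric sequences (e.g. Y-X-Y) the
    middle angle lies in [0, 180] deg; for asymmetric (Tait-Bryan) sequences in
    [-90, 90] deg. At gimbal lock the third angle is set to zero, the first
    angle carries the free rotation, and ``degenerate`` is True.
    """
    seq = _check_sequence(seq)
    R = _check_matrix(R)
    rot = Rotation.from_matrix(R)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        angles = rot.as_euler(seq, degrees=True)
    degenerate = any("imbal" in str(w.message) for w in caught)
    return np.asarray(angles, dtype=float), degenerate


def euler_intrinsic_batch(
    matrices: np.ndarray, seq: str, band_deg: float = 1.0
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised Euler decomposition of stacked rotation matrices.

    Returns ``(angles (n, 3) deg, near_gimbal (n,) bool)`` where the flag marks
    frames whose middle angle lies within ``band_deg`` of the degenerate band
    (0/180 deg for symmetric sequences, +/-90 deg for asymmetric ones).
    """
    seq = _check_sequence(seq)
    rot = Rotation.from_matrix(np.asarray(matrices, dtype=float))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        angles = rot.as_euler(seq, degrees=True)
    angles = np.atleast_2d(angles)
    a2 = angles[:, 1]
    if seq[0] == seq[2]:
        flag = (a2 < band_deg) | (a2 > 180.0 - band_deg)
    else:
        flag = np.abs(np.abs(a2) - 90.0) < band_deg
    return angles, flag


def unwrap_angles(values, period: float = 360.0) -> np.ndarray:
    """Remove modular jumps so successive differences stay within half a period.

    Output is elementwise congruent to the input modulo ``period`` and the
    operation is idempotent.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        return values.copy()
    if period <= 0:
        raise ParameterError("period must be positive")
    return np.unwrap(values, period=period)


def estimate_rotation_center(marker_series, min_frames: int = 10) -> tuple[np.ndarray, float]:
    """Estimate the fixed centre of rotation of a rigidly rotating marker set.

    Each marker is assumed to move on a sphere around a common, fixed centre
    (ball-joint pivot). The centre is found by a linear least-squares sphere
    fit with a shared centre and per-marker radii: for marker ``m`` and frame
    ``i``, ``|p_mi - c|^2 = r_m^2`` linearises to
    ``2 p_mi . c - d_m = |p_mi|^2`` with ``d_m = |c|^2 - r_m^2``.

    Parameters
    ----------
    marker_series : array (n_frames, n_markers, 3)
        Marker positions (mm) in a fixed reference frame.
    min_frames : int
        Minimum number of frames required.

    Returns
    -------
    centre : (3,) array (mm)
    residual : float
        RMS deviation of marker-to-centre distances from the fitted radii (mm).
    """
    pts = np.asarray(marker_series, dtype=float)
    if pts.ndim != 3 or pts.shape[2] != 3:
        raise ParameterError("marker_series must have shape (n_frames, n_markers, 3)")
    n_frames, n_markers = pts.shape[:2]
    if n_frames < min_frames:
        raise RankDeficiencyError(f"need at least {min_frames} frames, got {n_frames}")
    if n_markers < 1:
        raise ParameterError("need at least one marker")

    rows = n_frames * n_markers
    A = np.zeros((rows, 3 + n_markers))
    b = np.zeros(rows)
    for m in range(n_markers):
        sl = slice(m * n_frames, (m + 1) * n_frames)
        A[sl, :3] = 2.0 * pts[:, m, :]
        A[sl, 3 + m] = -1.0
        b[sl] = np.sum(pts[:, m, :] ** 2, axis=1)
    # centre the columns' information content check via singular values
    sv = np.linalg.svd(A, compute_uv=False)
    if sv[-1] < 1e-9 * sv[0]:
        raise RankDeficiencyError(
            "marker motion does not constrain a rotation centre (no rotation observed)"
        )
    x, *_ = np.linalg.lstsq(A, b, rcond=None)
    centre = x[:3]
    dists = np.linalg.norm(pts - centre[None, None, :], axis=2)  # (frames, markers)
    radii = dists.mean(axis=0)
    residual = float(np.sqrt(np.mean((dists - radii[None, :]) ** 2)))
    return centre, residual
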