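"""Timestamped measurement containers shared by the simulator and the two
angle-computation methods.

All series are uniformly sampled. Positions are millimetres, angles degrees,
quaternions scalar-first ``[w, x, y, z]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError

__all__ = ["AngleSeries", "KeypointSeries", "OrientationSeries", "JointAngleTable"]

# the four angle sets entering the agreement analysis (forearm
# pronation-supination is tracked but excluded from agreement)
ANGLE_CHANNELS = (
    "shoulder_plane_of_elevation",
    "shoulder_angle_of_elevation",
    "shoulder_rotation",
    "elbow_flexion",
)
ALL_CHANNELS = ANGLE_CHANNELS + ("pronation",)


def _check_uniform(times: np.ndarray, rate: float) -> None:
    times = np.asarray(times, dtype=float)
    if times.ndim != 1:
        raise ParameterError("timestamps must be 1-D")
    if len(times) > 1:
        expected = len(times) - 1
        span = rate * (times[-1] - times[0])
        if abs(span - expected) > 0.5:
            raise ParameterError(
                f"timestamps inconsistent with rate {rate} Hz: span covers "
                f"{span:.2f} intervals for {expected} samples"
            )
        if np.any(np.diff(times) <= 0):
            raise ParameterError("timestamps must be strictly increasing")


@dataclass
class AngleSeries:
    """A single uniformly sampled angle channel (degrees)."""

    times: np.ndarray
    values: np.ndarray
    rate: float
    label: str = ""

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.times) != len(self.values):
            raise ParameterError("timestamps and values must have equal length")
        _check_uniform(self.times, self.rate)

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class KeypointSeries:
    """Named 3-D keypoint trajectories (mm) with per-point validity flags."""

    times: np.ndarray
    names: tuple[str, ...]
    points: np.ndarray  # (n_frames, n_points, 3) mm
    valid: np.ndarray  # (n_frames, n_points) bool
    rate: float

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.points = np.asarray(self.points, dtype=float)
        self.names = tuple(self.names)
        if self.points.shape != (len(self.times), len(self.names), 3):
            raise ParameterError("points must have shape (n_frames, n_points, 3)")
        if self.valid is None:
            self.valid = np.ones(self.points.shape[:2], dtype=bool)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.valid.shape != self.points.shape[:2]:
            raise ParameterError("valid must have shape (n_frames, n_points)")
        _check_uniform(self.times, self.rate)

    def __len__(self) -> int:
        return len(self.times)

    def index(self, name: str) -> int:
        return self.names.index(name)

    def get(self, name: str) -> np.ndarray:
        return self.points[:, self.index(name), :]


@dataclass
class OrientationSeries:
    """Named per-segment unit-quaternion trajectories."""

    times: np.ndarray
    segments: tuple[str, ...]
    quats: np.ndarray  # (n_frames, n_segments, 4) [w,x,y,z]
    rate: float

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.quats = np.asarray(self.quats, dtype=float)
        self.segments = tuple(self.segments)
        if self.quats.shape != (len(self.times), len(self.segments), 4):
            raise ParameterError("quats must have shape (n_frames, n_segments, 4)")
        norms = np.linalg.norm(self.quats, axis=2)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ParameterError("orientation quaternions must be unit norm")
        _check_uniform(self.times, self.rate)

    def __len__(self) -> int:
        return len(self.times)

    def get(self, segment: str) -> np.ndarray:
        return self.quats[:, self.segments.index(segment), :]


@dataclass
class JointAngleTable:
    """Per-frame joint-angle channels (degrees) plus trial metadata.

    ``gimbal_flag`` marks frames where the shoulder Euler decomposition is
    within its degenerate band and the plane-of-elevation/rotation split is
    unreliable.
    """

    times: np.ndarray
    rate: float
    channels: dict[str, np.ndarray]
    meta: dict = field(default_factory=dict)
    gimbal_flag: np.ndarray | None = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        n = len(self.times)
        for name, vals in self.channels.items():
            vals = np.asarray(vals, dtype=float)
            if len(vals) != n:
                raise ParameterError(f"channel {name!r} length != timestamps")
            self.channels[name] = vals
        if self.gimbal_flag is None:
            self.gimbal_flag = np.zeros(n, dtype=bool)
        self.gimbal_flag = np.asarray(self.gimbal_flag, dtype=bool)
        _check_uniform(self.times, self.rate)

    def __len__(self) -> int:
        return len(self.times)

    def channel(self, name: str) -> AngleSeries:
        """A single angle channel as a standalone series."""
        return AngleSeries(
            times=self.times.copy(),
            values=self.channels[name].copy(),
            rate=self.rate,
            label=name,
        )

    def slice(self, start: int, stop: int) -> "JointAngleTable":
        n = stop - start
        times = np.arange(n) / self.rate + self.times[0]
        return JointAngleTable(
            times=times,
            rate=self.rate,
            channels={k: v[start:stop].copy() for k, v in self.channels.items()},
            meta=dict(self.meta),
            gimbal_flag=self.gimbal_flag[start:stop].copy(),
        )
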