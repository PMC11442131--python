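"""Finger joint kinematics: segment frames, Cardan angles, filtering, baseline.

Conventions used throughout the package:

* Angles are degrees at every module boundary; radians never cross one.
* Each angle frame is the 4-vector ``(dip_flex, pip_flex, mcp_flex, abd)``.
* Flexion is positive for palmar rotation (rotation about the joint +X
  axis); abduction, measured at the MCP only, is positive away from the
  middle finger (rotation about +Z).  The bone long axis is +Y.
* Relative segment rotations decompose by the Cardan XYZ sequence,
  ``R = Rx(x) @ Ry(y) @ Rz(z)``; x is read as flexion, z as abduction,
  y is reported but unused downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from numpy.typing import ArrayLike, NDArray
from scipy import signal

from graspquant.taxonomy import check_finger

ANGLE_COLUMNS: tuple[str, ...] = ("dip_flex_deg", "pip_flex_deg", "mcp_flex_deg", "abd_deg")

#: Kinematic chain segments of one finger, proximal to distal.
SEGMENTS: tuple[str, ...] = ("metacarpal", "proximal", "middle", "distal")

#: Anatomical ranges used for validation and for signal normalization:
#: flexion in [-10, 110] degrees, abduction in [-30, 30] degrees.
FLEXION_RANGE: tuple[float, float] = (-10.0, 110.0)
ABDUCTION_RANGE: tuple[float, float] = (-30.0, 30.0)


@dataclass(frozen=True)
class AngleStream:
    """A time-indexed series of 4-angle frames for one finger.

    ``frames`` has shape (n_frames, 4) with columns
    (DIP flexion, PIP flexion, MCP flexion, abduction), degrees.
    Time origin is frame 0; the sampling rate is constant.
    """

    finger: str
    sampling_rate: float
    frames: NDArray[np.float64]

    def __post_init__(self) -> None:
        check_finger(self.finger)
        frames = np.asarray(self.frames, dtype=np.float64)
        if frames.ndim != 2 or frames.shape[1] != 4:
            raise ValueError(f"frames must have shape (n, 4), got {frames.shape}")
        if frames.shape[0] < 1:
            raise ValueError("AngleStream needs at least one frame")
        if not np.all(np.isfinite(frames)):
            raise ValueError("AngleStream frames must be finite")
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be positive")
        object.__setattr__(self, "frames", frames)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.sampling_rate

    def with_frames(self, frames: ArrayLike) -> "AngleStream":
        return replace(self, frames=np.asarray(frames, dtype=np.float64))


@dataclass(frozen=True)
class FilterSpec:
    """Zero-lag low-pass Butterworth filter settings.

    Defaults follow standard hand-tracking practice: fourth order,
    15 Hz cut-off for marker trajectories and 5 Hz for angle streams,
    applied forward-backward so the net phase delay is zero.
    """

    cutoff_hz: float
    sampling_rate: float
    order: int = 4
    zero_lag: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.cutoff_hz < self.sampling_rate / 2:
            raise ValueError(
                f"cutoff ({self.cutoff_hz} Hz) must lie in (0, Nyquist="
                f"{self.sampling_rate / 2} Hz)"
            )
        if self.order < 1:
            raise ValueError("order must be >= 1")


@dataclass(frozen=True)
class BaselinePosture:
    """Flat-hand zero reference: per-joint angles averaged over 1 s."""

    finger: str
    zero_angles: NDArray[np.float64] = field(repr=False)

    def __post_init__(self) -> None:
        check_finger(self.finger)
        z = np.asarray(self.zero_angles, dtype=np.float64)
        if z.shape != (4,) or not np.all(np.isfinite(z)):
            raise ValueError("zero_angles must be a finite 4-vector")
        object.__setattr__(self, "zero_angles", z)


class DegenerateGeometryError(ValueError):
    """Raised when marker geometry cannot define a segment frame."""


class GimbalLockWarning(UserWarning):
    """Cardan Y angle at +-90 degrees: x and z are not separable."""


def segment_frame(markers: ArrayLike) -> tuple[NDArray[np.float64], NDArray[np.float64]]:
    """Build a right-handed orthonormal frame from >= 3 non-collinear markers.

    The origin is the first marker; X points from marker 1 to marker 2;
    Z is normal to the plane of the first three markers (X cross the
    1->3 direction); Y completes the right-handed triad.

    Returns ``(rotation, origin)`` where the rotation's columns are the
    frame axes expressed in lab coordinates.
    """
    pts = np.asarray(markers, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[0] < 3 or pts.shape[1] != 3:
        raise ValueError(f"need >= 3 3-D markers, got array of shape {pts.shape}")
    origin = pts[0]
    v1 = pts[1] - pts[0]
    v2 = pts[2] - pts[0]
    normal = np.cross(v1, v2)
    area2 = np.linalg.norm(normal)
    scale = max(np.linalg.norm(v1), np.linalg.norm(v2))
    if scale == 0 or area2 <= 1e-12 * scale**2:
        raise DegenerateGeometryError("markers are collinear; frame undefined")
    x = v1 / np.linalg.norm(v1)
    z = normal / area2
    y = np.cross(z, x)
    rot = np.column_stack([x, y, z])
    return rot, origin


def cardan_compose(x_deg: float, y_deg: float, z_deg: float) -> NDArray[np.float64]:
    """Compose ``R = Rx(x) @ Ry(y) @ Rz(z)`` from Cardan XYZ angles in degrees."""
    x, y, z = np.deg2rad([x_deg, y_deg, z_deg])
    cx, sx = np.cos(x), np.sin(x)
    cy, sy = np.cos(y), np.sin(y)
    cz, sz = np.cos(z), np.sin(z)
    rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return rx @ ry @ rz


def cardan_xyz(rotation: ArrayLike) -> tuple[float, float, float]:
    """Decompose a rotation matrix by the Cardan XYZ sequence, in degrees.

    For ``R = Rx(x) @ Ry(y) @ Rz(z)``: ``y = asin(R[0, 2])``,
    ``x = atan2(-R[1, 2], R[2, 2])``, ``z = atan2(-R[0, 1], R[0, 0])``.

    At gimbal lock (|y| = 90 deg, unreachable for physiological finger
    joints) only x + z (or x - z) is determined; the convention here
    assigns the whole rotation to x and sets z = 0, with a warning.
    """
    r = np.asarray(rotation, dtype=np.float64)
    if r.shape != (3, 3):
        raise ValueError("rotation must be 3x3")
    if not np.allclose(r.T @ r, np.eye(3), atol=1e-8):
        raise ValueError("rotation must be orthonormal")
    if np.linalg.det(r) < 0:
        raise ValueError("rotation must be right-handed (det = +1)")
    sy = np.clip(r[0, 2], -1.0, 1.0)
    if abs(abs(sy) - 1.0) < 1e-12:
        warnings.warn("gimbal lock: |y| = 90 deg; resolving with z := 0", GimbalLockWarning)
        y = np.arcsin(sy)
        x = np.arctan2(r[2, 1], r[1, 1])
        z = 0.0
    else:
        y = np.arcsin(sy)
        x = np.arctan2(-r[1, 2], r[2, 2])
        z = np.arctan2(-r[0, 1], r[0, 0])
    return float(np.rad2deg(x)), float(np.rad2deg(y)), float(np.rad2deg(z))


def joint_angles(
    proximal_frame: ArrayLike, distal_frame: ArrayLike
) -> tuple[float, float]:
    """Flexion and abduction of a joint from its adjacent segment frames.

    The relative rotation of the distal segment with respect to the
    proximal one is decomposed by the Cardan XYZ sequence; x is read as
    flexion (positive palmar) and z as abduction (positive away from
    the middle finger).  Callers discard abduction at the DIP and PIP,
    where it is not measured.
    """
    prox = np.asarray(proximal_frame, dtype=np.float64)
    dist = np.asarray(distal_frame, dtype=np.float64)
    rel = prox.T @ dist
    x, _y, z = cardan_xyz(rel)
    return x, z


def angles_from_markers(
    markers: dict[str, ArrayLike], sampling_rate: float, finger: str
) -> AngleStream:
    """Joint angles from per-segment marker trajectories.

    ``markers`` maps each chain segment name (see :data:`SEGMENTS`) to
    an array of shape (n_frames, n_markers, 3) in mm.  Per frame, a
    frame is constructed for every segment and adjacent segments are
    decomposed by the Cardan XYZ sequence: flexion is kept at every
    joint, abduction at the MCP only.
    """
    arrs = {}
    for seg in SEGMENTS:
        if seg not in markers:
            raise ValueError(f"missing marker trajectories for segment {seg!r}")
        arrs[seg] = np.asarray(markers[seg], dtype=np.float64)
    n = arrs[SEGMENTS[0]].shape[0]
    frames = np.empty((n, 4))
    for f in range(n):
        rots = {seg: segment_frame(arrs[seg][f])[0] for seg in SEGMENTS}
        mcp_flex, mcp_abd = joint_angles(rots["metacarpal"], rots["proximal"])
        pip_flex, _ = joint_angles(rots["proximal"], rots["middle"])
        dip_flex, _ = joint_angles(rots["middle"], rots["distal"])
        frames[f] = (dip_flex, pip_flex, mcp_flex, mcp_abd)
    return AngleStream(finger=finger, sampling_rate=sampling_rate, frames=frames)


def filter_zero_lag(series: ArrayLike, spec: FilterSpec) -> NDArray[np.float64]:
    """Forward-backward Butterworth low-pass along axis 0.

    Zero phase; DC gain exactly 1; amplitude gain at the cut-off is
    0.5 (the single-pass half-power point squared).  Edge effects are
    handled by symmetric reflection padding of length 3 * (order + 1).
    """
    arr = np.asarray(series, dtype=np.float64)
    padlen = 3 * (spec.order + 1)
    if arr.shape[0] <= padlen:
        raise ValueError(
            f"series of length {arr.shape[0]} too short to filter; "
            f"need > {padlen} samples"
        )
    sos = signal.butter(spec.order, spec.cutoff_hz, btype="low", fs=spec.sampling_rate, output="sos")
    return signal.sosfiltfilt(sos, arr, axis=0, padtype="even", padlen=padlen)


def filter_stream(stream: AngleStream, cutoff_hz: float = 5.0, order: int = 4) -> AngleStream:
    """Low-pass an angle stream (default: the 5 Hz angle cut-off)."""
    spec = FilterSpec(cutoff_hz=cutoff_hz, sampling_rate=stream.sampling_rate, order=order)
    return stream.with_frames(filter_zero_lag(stream.frames, spec))


def compute_baseline(calibration_stream: AngleStream, window_s: float = 1.0) -> BaselinePosture:
    """Average a flat-hand calibration recording over its first full second."""
    n = int(round(window_s * calibration_stream.sampling_rate))
    if calibration_stream.n_frames < n:
        raise ValueError(
            f"calibration stream has {calibration_stream.n_frames} frames; "
            f"{n} needed for a {window_s} s window"
        )
    zero = calibration_stream.frames[:n].mean(axis=0)
    return BaselinePosture(finger=calibration_stream.finger, zero_angles=zero)


def apply_baseline(stream: AngleStream, baseline: BaselinePosture) -> AngleStream:
    """Subtract the flat-hand zero posture frame-wise."""
    if stream.finger != baseline.finger:
        raise ValueError(
            f"finger mismatch: stream is {stream.finger!r}, baseline is {baseline.finger!r}"
        )
    return stream.with_frames(stream.frames - baseline.zero_angles)
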