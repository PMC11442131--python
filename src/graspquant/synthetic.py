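"""Synthetic finger-kinematic data with known ground truth.

Generates the three kinds of input the analysis pipeline consumes:

* static 1-s grasp trials at 125 Hz (one grasp template plus i.i.d.
  angular noise), emulating the training protocol of ten held
  repetitions per grasp;
* ADL-like angle streams: piecewise-constant grasp plateaus joined by
  short smoothstep transitions, with band-limited plateau jitter, plus
  the ground-truth plateau intervals;
* marker trajectories from a forward-kinematic chain, for round-trip
  testing of the angle-computation stage.

The per-grasp angle templates are fixed package constants.  They are
not measurements: no per-grasp joint angles are published for this
protocol, so the table is a plausible, versioned fixture whose one
load-bearing property — a minimum pairwise Euclidean separation of
15 degrees within each finger — is asserted at construction, so that
downstream classification tests measure pipeline correctness rather
than template luck.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.typing import NDArray

from graspquant.kinematics import (
    ABDUCTION_RANGE,
    SEGMENTS,
    AngleStream,
    DegenerateGeometryError,
    FLEXION_RANGE,
    FilterSpec,
    cardan_compose,
    filter_zero_lag,
)
from graspquant.taxonomy import FINGERS, check_finger, finger_grasps

#: Minimum pairwise Euclidean distance (degrees) between any two grasp
#: templates of one finger, asserted at construction.
MIN_TEMPLATE_SEPARATION_DEG = 15.0

# Base posture per grasp: (DIP flexion, PIP flexion, MCP flexion, abduction),
# degrees.  Chosen once for plausibility on a 15-degree grid: with every
# coordinate a multiple of 15 and all tuples distinct, any two templates
# differ by >= 15 degrees in at least one angle (and in Euclidean
# distance).  The per-angle separation matters because the pipeline's
# 5 Hz zero-lag filter limits a step's frame-to-frame slope to about
# 0.08 x step at 125 Hz: a grasp change must move some single angle by
# more than ~12.5 degrees for the 1-degree segmentation rule to see it.
_BASE_POSTURES: dict[str, tuple[float, float, float, float]] = {
    "adducted_thumb": (15.0, 15.0, 30.0, 0.0),
    "finger_extension": (0.0, 0.0, 15.0, 0.0),
    "lateral": (15.0, 45.0, 45.0, 0.0),
    "light_tool": (30.0, 60.0, 60.0, 0.0),
    "medium_wrap": (45.0, 75.0, 60.0, 0.0),
    "palmar_pinch": (15.0, 30.0, 60.0, 15.0),
    "parallel_extension": (0.0, 15.0, 45.0, 0.0),
    "power_sphere": (45.0, 60.0, 45.0, 15.0),
    "precision_disc": (30.0, 45.0, 45.0, 15.0),
    "precision_sphere": (30.0, 45.0, 30.0, 15.0),
    "prismatic_4_fingers": (30.0, 45.0, 75.0, 0.0),
    "tripod": (30.0, 30.0, 60.0, 15.0),
    "writing_tripod": (60.0, 75.0, 75.0, 0.0),
}

# Constant per-finger offsets: same-grasp templates differ across fingers
# while pairwise within-finger distances are preserved exactly.
_FINGER_OFFSETS: dict[str, tuple[float, float, float, float]] = {
    "index": (0.0, 0.0, 0.0, 0.0),
    "middle": (3.0, -2.0, 2.0, -2.0),
    "ring": (-3.0, 3.0, -2.0, 2.0),
    "little": (2.0, 4.0, -4.0, -1.0),
}

#: Default within-class angular noise SD (degrees) for static trials,
#: comparable to marker-derived joint-angle noise after 5 Hz filtering.
DEFAULT_STATIC_NOISE_SD = 2.0

#: Default plateau jitter SD (degrees) for ADL streams.  Post-filter
#: hold-still jitter must be well under the 1-degree segmentation
#: threshold for the piecewise-constant rule to be meaningful at all.
DEFAULT_ADL_NOISE_SD = 0.5


@dataclass(frozen=True)
class GraspTemplate:
    """Mean 4-angle posture of one grasp for one finger, with noise SD."""

    finger: str
    grasp: str
    mean_angles: NDArray[np.float64]
    within_class_sd: NDArray[np.float64] = field(
        default_factory=lambda: np.full(4, DEFAULT_STATIC_NOISE_SD)
    )

    def __post_init__(self) -> None:
        check_finger(self.finger)
        if self.grasp not in finger_grasps(self.finger):
            raise ValueError(
                f"grasp {self.grasp!r} is not in the training subset of the "
                f"{self.finger} finger"
            )
        mean = np.asarray(self.mean_angles, dtype=np.float64)
        sd = np.asarray(self.within_class_sd, dtype=np.float64)
        if mean.shape != (4,) or sd.shape != (4,):
            raise ValueError("mean_angles and within_class_sd must be 4-vectors")
        lo, hi = FLEXION_RANGE
        if np.any(mean[:3] < lo) or np.any(mean[:3] > hi):
            raise ValueError(f"flexion angles must lie in [{lo}, {hi}] deg")
        alo, ahi = ABDUCTION_RANGE
        if not alo <= mean[3] <= ahi:
            raise ValueError(f"abduction must lie in [{alo}, {ahi}] deg")
        if np.any(sd < 0):
            raise ValueError("within_class_sd must be non-negative")
        object.__setattr__(self, "mean_angles", mean)
        object.__setattr__(self, "within_class_sd", sd)


@dataclass(frozen=True)
class SyntheticADLSpec:
    """Recipe for a ground-truthed ADL-like angle stream."""

    finger: str
    segment_labels: tuple[str, ...]
    segment_durations: tuple[float, ...]
    transition_duration: float = 0.08
    noise_sd: float = DEFAULT_ADL_NOISE_SD
    sampling_rate: float = 125.0
    seed: int = 0

    def __post_init__(self) -> None:
        check_finger(self.finger)
        object.__setattr__(self, "segment_labels", tuple(self.segment_labels))
        object.__setattr__(self, "segment_durations", tuple(self.segment_durations))
        if len(self.segment_labels) != len(self.segment_durations):
            raise ValueError("segment_labels and segment_durations differ in length")
        if len(self.segment_labels) == 0:
            raise ValueError("need at least one segment")
        if any(d <= 0 for d in self.segment_durations):
            raise ValueError("segment durations must be positive")
        if self.transition_duration < 0:
            raise ValueError("transition_duration must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        allowed = finger_grasps(self.finger)
        for label in self.segment_labels:
            if label not in allowed:
                raise ValueError(
                    f"label {label!r} not in the {self.finger} finger subset"
                )


@dataclass(frozen=True)
class ChainGeometry:
    """Rigid-segment geometry of one finger for forward kinematics.

    ``segment_lengths`` are (metacarpal, proximal, middle, distal
    phalanx) lengths in mm along the bone (+Y) axis.  Each segment
    carries >= 3 non-collinear markers given in its local frame.
    """

    segment_lengths: tuple[float, float, float, float]
    marker_offsets: dict[str, NDArray[np.float64]]

    def __post_init__(self) -> None:
        if len(self.segment_lengths) != 4 or any(l <= 0 for l in self.segment_lengths):
            raise ValueError("segment_lengths must be four positive lengths (mm)")
        offsets = {}
        for seg in SEGMENTS:
            if seg not in self.marker_offsets:
                raise ValueError(f"missing marker offsets for segment {seg!r}")
            pts = np.asarray(self.marker_offsets[seg], dtype=np.float64)
            if pts.ndim != 2 or pts.shape[0] < 3 or pts.shape[1] != 3:
                raise ValueError(f"segment {seg!r} needs >= 3 3-D marker offsets")
            area2 = np.linalg.norm(np.cross(pts[1] - pts[0], pts[2] - pts[0]))
            if area2 <= 1e-9:
                raise DegenerateGeometryError(
                    f"segment {seg!r} markers are collinear (triangle area 0)"
                )
            offsets[seg] = pts
        object.__setattr__(self, "marker_offsets", offsets)


def default_geometry() -> ChainGeometry:
    """Index-finger-like chain with a marker triad per segment.

    Marker triads are axis-aligned in each segment's local frame, so
    the frame-construction convention of :func:`~graspquant.kinematics.
    segment_frame` recovers the segment rotation exactly.
    """
    triad = np.array([[0.0, 0.0, 0.0], [8.0, 0.0, 0.0], [0.0, 8.0, 0.0]])
    return ChainGeometry(
        segment_lengths=(65.0, 40.0, 25.0, 18.0),
        marker_offsets={seg: triad.copy() for seg in SEGMENTS},
    )


def default_templates() -> list[GraspTemplate]:
    """The versioned per-finger template table: 13 + 12 + 8 + 8 entries.

    Asserts the minimum within-finger pairwise separation before
    returning; the table cannot silently drift below it.
    """
    templates: list[GraspTemplate] = []
    for finger in FINGERS:
        offset = np.array(_FINGER_OFFSETS[finger])
        finger_templates = [
            GraspTemplate(
                finger=finger,
                grasp=grasp,
                mean_angles=np.array(_BASE_POSTURES[grasp]) + offset,
            )
            for grasp in finger_grasps(finger)
        ]
        means = np.stack([t.mean_angles for t in finger_templates])
        diffs = means[:, None, :] - means[None, :, :]
        eucl = np.linalg.norm(diffs, axis=-1)
        linf = np.abs(diffs).max(axis=-1)
        np.fill_diagonal(eucl, np.inf)
        np.fill_diagonal(linf, np.inf)
        for name, sep in (("Euclidean", float(eucl.min())), ("per-angle", float(linf.min()))):
            if sep < MIN_TEMPLATE_SEPARATION_DEG - 1e-9:
                raise AssertionError(
                    f"{finger} templates have minimum {name} separation "
                    f"{sep:.2f} deg (< {MIN_TEMPLATE_SEPARATION_DEG})"
                )
        templates.extend(finger_templates)
    return templates


def templates_for(finger: str, templates: list[GraspTemplate] | None = None) -> dict[str, GraspTemplate]:
    """Map grasp name -> template for one finger."""
    check_finger(finger)
    if templates is None:
        templates = default_templates()
    return {t.grasp: t for t in templates if t.finger == finger}


def sample_static_trial(
    template: GraspTemplate,
    duration_s: float = 1.0,
    fs: float = 125.0,
    noise_sd: float | None = None,
    seed: int = 0,
) -> AngleStream:
    """One held static grasp trial: template mean + i.i.d. Gaussian noise.

    ``noise_sd`` may be a scalar overriding the template's per-joint SD.
    """
    if duration_s <= 0 or fs <= 0:
        raise ValueError("duration_s and fs must be positive")
    if noise_sd is None:
        sd = template.within_class_sd
    else:
        if noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        sd = np.full(4, float(noise_sd))
    n = int(round(duration_s * fs))
    rng = np.random.default_rng(seed)
    frames = template.mean_angles + rng.standard_normal((n, 4)) * sd
    return AngleStream(finger=template.finger, sampling_rate=fs, frames=frames)


def _smoothstep(n: int) -> NDArray[np.float64]:
    """n interior samples of the cubic smoothstep ramp on (0, 1)."""
    t = (np.arange(1, n + 1)) / (n + 1)
    return t * t * (3.0 - 2.0 * t)


def _band_limited_noise(
    rng: np.random.Generator, n: int, fs: float, sd: float
) -> NDArray[np.float64]:
    """Gaussian noise low-passed at the 5 Hz angle cut-off, rescaled to sd.

    Emulates residual joint-angle jitter after the pipeline's angle
    filtering: smooth frame to frame, so plateaus stay below the
    segmentation threshold, as post-filter real data would.
    """
    white = rng.standard_normal((n, 4))
    cutoff = min(5.0, 0.4 * fs)
    spec = FilterSpec(cutoff_hz=cutoff, sampling_rate=fs)
    padlen = 3 * (spec.order + 1)
    if n <= padlen:
        return white * sd
    smooth = filter_zero_lag(white, spec)
    scale = smooth.std(axis=0, ddof=0)
    scale[scale == 0] = 1.0
    return smooth / scale * sd


def sample_adl_stream(
    spec: SyntheticADLSpec,
    templates: list[GraspTemplate] | None = None,
) -> tuple[AngleStream, list[tuple[str, int, int]]]:
    """Piecewise-constant ADL-like stream plus ground-truth plateaus.

    Returns ``(stream, truth)`` where ``truth`` lists
    ``(label, start_frame, end_frame)`` for each grasp plateau,
    0-based half-open.  Transition ramps between plateaus are excluded
    from the ground truth; at realistic re-posturing speeds their
    frame-to-frame deltas exceed the 1-degree rule and segment out on
    their own.
    """
    by_name = templates_for(spec.finger, templates)
    fs = spec.sampling_rate
    n_trans = int(round(spec.transition_duration * fs))

    chunks: list[NDArray[np.float64]] = []
    truth: list[tuple[str, int, int]] = []
    cursor = 0
    for i, (label, dur) in enumerate(zip(spec.segment_labels, spec.segment_durations)):
        mean = by_name[label].mean_angles
        n = int(round(dur * fs))
        if n < 1:
            raise ValueError(f"segment {i} shorter than one frame at {fs} Hz")
        chunks.append(np.tile(mean, (n, 1)))
        truth.append((label, cursor, cursor + n))
        cursor += n
        if i + 1 < len(spec.segment_labels) and n_trans > 0:
            nxt = by_name[spec.segment_labels[i + 1]].mean_angles
            ramp = mean + _smoothstep(n_trans)[:, None] * (nxt - mean)
            chunks.append(ramp)
            cursor += n_trans

    frames = np.vstack(chunks)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        frames = frames + _band_limited_noise(rng, frames.shape[0], fs, spec.noise_sd)
    else:
        # noiseless plateaus must satisfy the segmentation criterion exactly
        for _label, a, b in truth:
            deltas = np.abs(np.diff(frames[a:b], axis=0))
            assert deltas.size == 0 or deltas.max() < 1.0

    stream = AngleStream(finger=spec.finger, sampling_rate=fs, frames=frames)
    return stream, truth


def forward_kinematics_markers(
    angles: AngleStream, geometry: ChainGeometry
) -> dict[str, NDArray[np.float64]]:
    """Pose the marker triads of a 4-segment finger chain frame by frame.

    The metacarpal is the fixed root (identity orientation, origin 0);
    each phalanx attaches at the distal end of its parent bone (+Y
    axis) and rotates by Rx(flexion) — with an additional Rz(abduction)
    at the MCP, matching the Cardan XYZ convention with y = 0.

    Returns segment name -> array of shape (n_frames, n_markers, 3), mm.
    """
    lo, hi = FLEXION_RANGE
    if np.any(angles.frames[:, :3] < lo - 1e-9) or np.any(angles.frames[:, :3] > hi + 1e-9):
        raise ValueError("flexion angles outside anatomical range")
    alo, ahi = ABDUCTION_RANGE
    if np.any(angles.frames[:, 3] < alo - 1e-9) or np.any(angles.frames[:, 3] > ahi + 1e-9):
        raise ValueError("abduction angles outside anatomical range")

    lengths = dict(zip(SEGMENTS, geometry.segment_lengths))
    n = angles.n_frames
    out = {
        seg: np.empty((n, geometry.marker_offsets[seg].shape[0], 3))
        for seg in SEGMENTS
    }
    eye = np.eye(3)
    for f in range(n):
        dip, pip_, mcp, abd = angles.frames[f]
        rots = {
            "metacarpal": eye,
            "proximal": cardan_compose(mcp, 0.0, abd),
        }
        rots["middle"] = rots["proximal"] @ cardan_compose(pip_, 0.0, 0.0)
        rots["distal"] = rots["middle"] @ cardan_compose(dip, 0.0, 0.0)
        origin = np.zeros(3)
        for seg in SEGMENTS:
            r = rots[seg]
            out[seg][f] = origin + geometry.marker_offsets[seg] @ r.T
            origin = origin + r @ np.array([0.0, lengths[seg], 0.0])
    return out
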