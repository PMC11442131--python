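"""Static-posture extraction and the 1-degree piecewise-constant rule.

Training trials are averaged over a 1-s window into one posture.  ADL
streams are partitioned into maximal runs of frames in which no joint
angle changes by more than the threshold (default 1 degree) between
consecutive frames; a supra-threshold change in any of the four angles
starts a new segment at the later frame.  Each run, averaged, is one
grasp instance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.typing import NDArray

from graspquant.kinematics import AngleStream
from graspquant.taxonomy import check_finger


@dataclass(frozen=True)
class SegmentationConfig:
    """Parameters of the piecewise-constant segmentation rule.

    ``threshold_deg`` is compared against the absolute consecutive-frame
    difference of each of the four angles; exceeding it in any angle
    opens a new segment.  ``min_frames`` (default 1, i.e. no minimum)
    drops shorter runs for exploratory use only.
    """

    threshold_deg: float = 1.0
    min_frames: int = 1

    def __post_init__(self) -> None:
        if not self.threshold_deg > 0:
            raise ValueError("threshold_deg must be positive")
        if self.min_frames < 1:
            raise ValueError("min_frames must be >= 1")


@dataclass(frozen=True)
class GraspPosture:
    """One static grasp instance: the mean 4-angle vector of a frame run."""

    finger: str
    angles: NDArray[np.float64]
    source_interval: tuple[int, int]
    label: str | None = None

    def __post_init__(self) -> None:
        check_finger(self.finger)
        a = np.asarray(self.angles, dtype=np.float64)
        if a.shape != (4,) or not np.all(np.isfinite(a)):
            raise ValueError("angles must be a finite 4-vector")
        start, end = self.source_interval
        if end - start < 1:
            raise ValueError("source_interval must span >= 1 frame")
        object.__setattr__(self, "angles", a)
        object.__setattr__(self, "source_interval", (int(start), int(end)))

    @property
    def n_frames(self) -> int:
        return self.source_interval[1] - self.source_interval[0]

    def with_label(self, label: str) -> "GraspPosture":
        return GraspPosture(self.finger, self.angles, self.source_interval, label)


def extract_training_posture(stream: AngleStream, window_s: float = 1.0) -> GraspPosture:
    """Average the first ``window_s`` seconds of a held trial into one posture."""
    n = int(round(window_s * stream.sampling_rate))
    if stream.n_frames < n:
        raise ValueError(
            f"stream has {stream.n_frames} frames, {n} needed for a "
            f"{window_s} s window"
        )
    return GraspPosture(
        finger=stream.finger,
        angles=stream.frames[:n].mean(axis=0),
        source_interval=(0, n),
    )


def segment_boundaries(
    frames: NDArray[np.float64], threshold_deg: float
) -> list[tuple[int, int]]:
    """Half-open intervals of the maximal sub-threshold runs.

    A boundary is placed after frame i whenever
    ``max_j |frames[i+1, j] - frames[i, j]| > threshold``; the later
    frame owns the new segment.  The intervals tile ``[0, n)`` exactly.
    """
    n = frames.shape[0]
    if n == 0:
        raise ValueError("cannot segment an empty stream")
    deltas = np.abs(np.diff(frames, axis=0)).max(axis=1)
    breaks = np.flatnonzero(deltas > threshold_deg) + 1
    edges = np.concatenate([[0], breaks, [n]])
    return [(int(a), int(b)) for a, b in zip(edges[:-1], edges[1:])]


def segment_adl(
    stream: AngleStream, cfg: SegmentationConfig | None = None
) -> list[GraspPosture]:
    """Partition an ADL stream into grasp instances by the threshold rule.

    Returns per-segment mean postures in stream order.  With the default
    ``min_frames=1`` the source intervals tile ``[0, n_frames)``.
    """
    cfg = cfg or SegmentationConfig()
    if stream.n_frames < 2:
        raise ValueError("segmentation needs at least 2 frames")
    intervals = segment_boundaries(stream.frames, cfg.threshold_deg)
    postures = [
        GraspPosture(
            finger=stream.finger,
            angles=stream.frames[a:b].mean(axis=0),
            source_interval=(a, b),
        )
        for a, b in intervals
        if b - a >= cfg.min_frames
    ]
    return postures


def postures_to_batch(postures: list[GraspPosture]) -> list[GraspPosture]:
    """Order-preserving batch of postures for the encoding stage."""
    return list(postures)
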