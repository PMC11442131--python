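"""Single pipeline configuration: every stage constant in one place."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    """All tunable constants of the grasp-quantification pipeline.

    Defaults are the study conditions: 125 Hz capture, fourth-order
    zero-lag Butterworth filtering at 15 Hz (markers) and 5 Hz
    (angles), the 1-degree segmentation rule, 224-pixel scalogram
    images, and the fixed training protocol (lr 0.001, batch 32, 100
    epochs, 30% validation).  Synthetic-data fields control only the
    generator, not the analysis.
    """

    sampling_rate_hz: float = 125.0
    filter_order: int = 4
    marker_cutoff_hz: float = 15.0
    angle_cutoff_hz: float = 5.0
    segmentation_threshold_deg: float = 1.0
    segmentation_min_frames: int = 1
    image_size: int = 224
    signal_length: int = 1024
    n_scales: int = 64
    colormap: str = "grasp_hi_contrast"
    backbone: str = "pooled_mlp"
    learning_rate: float = 0.001
    batch_size: int = 32
    epochs: int = 100
    val_fraction: float = 0.3
    seed: int = 0
    # synthetic-data generation
    trials_per_grasp: int = 10
    static_noise_sd_deg: float = 2.0
    adl_noise_sd_deg: float = 0.5
    transition_duration_s: float = 0.08
    n_activities: int = 3
    segments_per_activity: int = 6
    fingers: tuple[str, ...] = ("index", "middle", "ring", "little")
    out_dir: str = "results"
    keep_images: bool = False

    def __post_init__(self) -> None:
        positive = (
            "sampling_rate_hz", "filter_order", "marker_cutoff_hz",
            "angle_cutoff_hz", "segmentation_threshold_deg", "image_size",
            "signal_length", "n_scales", "learning_rate", "batch_size",
            "epochs", "trials_per_grasp", "n_activities", "segments_per_activity",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.val_fraction < 1:
            raise ValueError("val_fraction must lie in (0, 1)")
        self.fingers = tuple(self.fingers)

    def to_file(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)
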