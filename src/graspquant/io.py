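"""Tidy-CSV and JSON interchange for angle streams, postures and truth.

The canonical interchange format is the tidy angle CSV with columns
``frame, time_s, finger, dip_flex_deg, pip_flex_deg, mcp_flex_deg,
abd_deg``; the sampling rate is recovered from the ``time_s`` column.
Round trips are lossless to well below 1e-9 degrees (values are
written in full repr precision).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from graspquant.kinematics import ANGLE_COLUMNS, AngleStream
from graspquant.segmentation import GraspPosture

STREAM_COLUMNS = ("frame", "time_s", "finger", *ANGLE_COLUMNS)


class SchemaError(ValueError):
    """A file does not conform to the expected tidy schema."""


def write_angle_csv(stream: AngleStream, path: str | Path) -> None:
    n = stream.n_frames
    df = pd.DataFrame(
        {
            "frame": np.arange(n),
            "time_s": np.arange(n) / stream.sampling_rate,
            "finger": stream.finger,
        }
    )
    for j, col in enumerate(ANGLE_COLUMNS):
        df[col] = stream.frames[:, j]
    df.to_csv(path, index=False, float_format="%.12g")


def read_angle_csv(path: str | Path) -> AngleStream:
    df = pd.read_csv(path)
    missing = [c for c in STREAM_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {', '.join(missing)}")
    fingers = df["finger"].unique()
    if len(fingers) != 1:
        raise SchemaError(f"{path}: expected a single finger, got {list(fingers)}")
    t = df["time_s"].to_numpy()
    if len(t) > 1:
        dt = np.diff(t)
        if dt.min() <= 0 or (dt.max() - dt.min()) > 1e-6 * dt.mean():
            raise SchemaError(f"{path}: time_s must increase at a constant rate")
        fs = 1.0 / dt.mean()
    else:
        fs = 125.0
    frames = df[list(ANGLE_COLUMNS)].to_numpy(dtype=np.float64)
    return AngleStream(finger=str(fingers[0]), sampling_rate=float(fs), frames=frames)


def write_postures_csv(postures: list[GraspPosture], path: str | Path) -> None:
    rows = []
    for i, p in enumerate(postures):
        a, b = p.source_interval
        rows.append(
            {
                "index": i,
                "start_frame": a,
                "end_frame": b,
                "n_frames": p.n_frames,
                "dip": p.angles[0],
                "pip": p.angles[1],
                "mcp": p.angles[2],
                "abd": p.angles[3],
                "finger": p.finger,
                "label": p.label or "",
            }
        )
    pd.DataFrame(
        rows,
        columns=[
            "index", "start_frame", "end_frame", "n_frames",
            "dip", "pip", "mcp", "abd", "finger", "label",
        ],
    ).to_csv(path, index=False, float_format="%.12g")


def read_postures_csv(path: str | Path) -> list[GraspPosture]:
    df = pd.read_csv(path, keep_default_na=False)
    needed = {"start_frame", "end_frame", "dip", "pip", "mcp", "abd", "finger"}
    missing = needed - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing column(s) {', '.join(sorted(missing))}")
    out = []
    for _, row in df.iterrows():
        label = str(row["label"]) if "label" in df.columns and row["label"] else None
        out.append(
            GraspPosture(
                finger=str(row["finger"]),
                angles=np.array([row["dip"], row["pip"], row["mcp"], row["abd"]]),
                source_interval=(int(row["start_frame"]), int(row["end_frame"])),
                label=label,
            )
        )
    return out


def write_ground_truth(truth: list[tuple[str, int, int]], path: str | Path) -> None:
    payload = [
        {"label": label, "start_frame": a, "end_frame": b} for label, a, b in truth
    ]
    Path(path).write_text(json.dumps(payload, indent=2))


def read_ground_truth(path: str | Path) -> list[tuple[str, int, int]]:
    payload = json.loads(Path(path).read_text())
    return [(d["label"], int(d["start_frame"]), int(d["end_frame"])) for d in payload]
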