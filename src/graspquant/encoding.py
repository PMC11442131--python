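"""Posture -> signal -> continuous wavelet transform -> 224x224 RGB image.

A static 4-angle posture has no time structure of its own, so it is
embedded as a deterministic 1-D signal before the wavelet transform: a
mixture of four sinusoids at fixed, well-separated frequencies (8, 16,
32, 64 cycles per window), one per joint angle, with amplitudes equal
to the angles normalized by their anatomical ranges.  The embedding is
injective up to normalization — distinct postures give distinct
signals — and each joint shows up as its own horizontal ridge in the
scalogram, so grasp differences become image-feature differences.

The scalogram is the magnitude of a Morlet continuous wavelet
transform over log-spaced scales covering half the lowest to twice the
highest embedding frequency.  Rendering min-max normalizes per image,
applies a gamma stretch (gamma = 0.5) to lift faint ridges, maps
through a named 256-entry RGB lookup table, and resamples bilinearly
to 224x224, the input contract of the image classifier.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pywt
from numpy.typing import NDArray
from PIL import Image

from graspquant.kinematics import ABDUCTION_RANGE, FLEXION_RANGE
from graspquant.segmentation import GraspPosture

#: Embedding frequencies (cycles per window), one per angle:
#: DIP flexion, PIP flexion, MCP flexion, abduction.
SIGNAL_FREQUENCIES: tuple[int, int, int, int] = (8, 16, 32, 64)

DEFAULT_SIGNAL_LENGTH = 1024
DEFAULT_N_SCALES = 64
IMAGE_SIZE = 224
WAVELET = "morl"
GAMMA = 0.5
#: Intensity bands used when mapping magnitudes through the colormap.
#: Posterizing into a few high-contrast bands turns ridges into crisp
#: contour-like features and makes the raster robust to sub-band
#: magnitude jitter between noisy replicates of the same grasp.
QUANT_LEVELS = 32


@dataclass(frozen=True)
class PostureSignal:
    """Fixed-length 1-D embedding of one posture (L samples per window)."""

    samples: NDArray[np.float64]
    posture: GraspPosture | None = None

    def __post_init__(self) -> None:
        s = np.asarray(self.samples, dtype=np.float64)
        if s.ndim != 1 or not np.all(np.isfinite(s)):
            raise ValueError("samples must be a finite 1-D array")
        object.__setattr__(self, "samples", s)

    @property
    def length(self) -> int:
        return self.samples.shape[0]


@dataclass(frozen=True)
class Scalogram:
    """|CWT| magnitudes, shape (n_scales, L), with the scale grid used."""

    magnitude: NDArray[np.float64]
    scales: NDArray[np.float64]
    wavelet: str = WAVELET

    def __post_init__(self) -> None:
        m = np.asarray(self.magnitude, dtype=np.float64)
        s = np.asarray(self.scales, dtype=np.float64)
        if m.ndim != 2 or m.shape[0] != s.shape[0]:
            raise ValueError("magnitude must be (n_scales, L) matching scales")
        if m.shape[0] < 32:
            raise ValueError("need at least 32 scales")
        if np.any(m < 0):
            raise ValueError("magnitudes must be non-negative")
        object.__setattr__(self, "magnitude", m)
        object.__setattr__(self, "scales", s)


@dataclass(frozen=True)
class ScalogramImage:
    """224x224 8-bit RGB raster plus the rendering metadata."""

    pixels: NDArray[np.uint8]
    colormap: str
    norm_bounds: tuple[float, float]

    def __post_init__(self) -> None:
        p = np.asarray(self.pixels)
        if p.shape != (IMAGE_SIZE, IMAGE_SIZE, 3) or p.dtype != np.uint8:
            raise ValueError(
                f"pixels must be uint8 of shape ({IMAGE_SIZE}, {IMAGE_SIZE}, 3)"
            )
        object.__setattr__(self, "pixels", p)


def _load_colormaps() -> dict[str, NDArray[np.uint8]]:
    maps: dict[str, NDArray[np.uint8]] = {}
    ref = resources.files("graspquant") / "data" / "colormap_grasp_hi_contrast.csv"
    with ref.open() as fh:
        rows = [r for r in csv.reader(fh) if r and not r[0].startswith("#")]
    lut = np.array([[int(v) for v in r] for r in rows[1:]], dtype=np.uint8)
    if lut.shape != (256, 3):
        raise ValueError(f"colormap fixture must be 256x3, got {lut.shape}")
    maps["grasp_hi_contrast"] = lut
    ramp = np.arange(256, dtype=np.uint8)
    maps["gray"] = np.stack([ramp, ramp, ramp], axis=1)
    return maps


_COLORMAPS = _load_colormaps()


def _normalize_angles(angles: NDArray[np.float64]) -> NDArray[np.float64]:
    """Map (dip, pip, mcp, abd) onto [-1, 1] by the anatomical ranges."""
    lo, hi = FLEXION_RANGE
    alo, ahi = ABDUCTION_RANGE
    flex = 2.0 * (angles[:3] - lo) / (hi - lo) - 1.0
    abd = 2.0 * (angles[3] - alo) / (ahi - alo) - 1.0
    return np.concatenate([flex, [abd]])


def posture_to_signal(posture: GraspPosture, length: int = DEFAULT_SIGNAL_LENGTH) -> PostureSignal:
    """Embed a posture as a 4-sinusoid mixture of length ``length``."""
    if not np.all(np.isfinite(posture.angles)):
        raise ValueError("posture angles must be finite")
    amp = _normalize_angles(posture.angles)
    t = np.arange(length)
    sig = np.zeros(length)
    for a, f in zip(amp, SIGNAL_FREQUENCIES):
        sig += a * np.sin(2.0 * np.pi * f * t / length)
    return PostureSignal(samples=sig, posture=posture)


def scale_grid(length: int = DEFAULT_SIGNAL_LENGTH, n_scales: int = DEFAULT_N_SCALES) -> NDArray[np.float64]:
    """Log-spaced scales spanning f1/2 .. 2*f4 cycles per window."""
    f_lo = SIGNAL_FREQUENCIES[0] / 2.0
    f_hi = SIGNAL_FREQUENCIES[-1] * 2.0
    fc = pywt.central_frequency(WAVELET)
    # high frequency -> small scale; grid ascending in scale
    return np.geomspace(fc * length / f_hi, fc * length / f_lo, n_scales)


def scale_for_frequency(freq_cycles_per_window: float, length: int = DEFAULT_SIGNAL_LENGTH) -> float:
    """Scale at which the Morlet center frequency equals the given frequency."""
    return pywt.central_frequency(WAVELET) * length / freq_cycles_per_window


def cwt(sig: PostureSignal, n_scales: int = DEFAULT_N_SCALES) -> Scalogram:
    """Morlet continuous wavelet transform magnitude of a posture signal."""
    if n_scales < 2:
        raise ValueError("n_scales must be >= 2")
    scales = scale_grid(sig.length, n_scales)
    coef, _freqs = pywt.cwt(sig.samples, scales, WAVELET, method="fft")
    return Scalogram(magnitude=np.abs(coef), scales=scales)


def render(scalogram: Scalogram, colormap: str = "grasp_hi_contrast") -> ScalogramImage:
    """Render the magnitude matrix as a fixed-size 8-bit RGB image.

    Per-image min-max normalization makes the raster invariant to
    positive scaling of the magnitudes; a constant (e.g. all-zero)
    scalogram maps uniformly to the colormap's low endpoint.
    """
    if colormap not in _COLORMAPS:
        raise ValueError(
            f"unknown colormap {colormap!r}; available: {sorted(_COLORMAPS)}"
        )
    mag = scalogram.magnitude
    lo = float(mag.min())
    hi = float(mag.max())
    if hi > lo:
        norm = (mag - lo) / (hi - lo)
    else:
        norm = np.zeros_like(mag)
    stretched = np.power(norm, GAMMA)
    img = Image.fromarray(stretched.astype(np.float32), mode="F")
    resized = np.asarray(
        img.resize((IMAGE_SIZE, IMAGE_SIZE), resample=Image.BILINEAR), dtype=np.float64
    )
    bands = np.clip(np.rint(resized * (QUANT_LEVELS - 1)), 0, QUANT_LEVELS - 1)
    idx = np.rint(bands * 255.0 / (QUANT_LEVELS - 1)).astype(np.uint8)
    pixels = _COLORMAPS[colormap][idx]
    return ScalogramImage(pixels=pixels, colormap=colormap, norm_bounds=(lo, hi))


def encode_posture(
    posture: GraspPosture,
    length: int = DEFAULT_SIGNAL_LENGTH,
    n_scales: int = DEFAULT_N_SCALES,
    colormap: str = "grasp_hi_contrast",
) -> ScalogramImage:
    """Posture -> signal -> CWT -> rendered image, in one step."""
    return render(cwt(posture_to_signal(posture, length), n_scales), colormap)


def encode_batch(
    postures: list[GraspPosture],
    out_dir: str | Path | None = None,
    name_prefix: str = "posture",
    **kwargs,
) -> list[ScalogramImage]:
    """Encode postures in order; optionally write lossless PNGs.

    Files are named ``<finger>_<label-or-prefix>_<index>.png``.
    """
    images = [encode_posture(p, **kwargs) for p in postures]
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for i, (posture, image) in enumerate(zip(postures, images)):
            stem = f"{posture.finger}_{posture.label or name_prefix}_{i:04d}"
            write_png(image, out / f"{stem}.png")
    return images


def write_png(image: ScalogramImage, path: str | Path) -> None:
    try:
        Image.fromarray(image.pixels, mode="RGB").save(path, format="PNG", compress_level=6)
    except OSError as exc:
        raise OSError(f"failed writing PNG {path}: {exc}") from exc


def read_png(path: str | Path, colormap: str = "grasp_hi_contrast") -> ScalogramImage:
    with Image.open(path) as img:
        pixels = np.asarray(img.convert("RGB"), dtype=np.uint8)
    return ScalogramImage(pixels=pixels, colormap=colormap, norm_bounds=(0.0, 1.0))
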