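"""Core in-memory containers shared across the pipeline.

All containers are plain dataclasses over numpy arrays: a calibrated
1-D pressure time series (:class:`SignalRecording`), the glottal area
waveform with its left/right hemi-areas (:class:`GlottalAreaWaveform`),
and a high-speed image stack (:class:`FrameStack`).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "SignalRecording",
    "GlottalAreaWaveform",
    "FrameStack",
]


@dataclass
class SignalRecording:
    """A calibrated 1-D pressure time series.

    Parameters
    ----------
    samples : ndarray
        Pressure in Pa.
    fs_hz : float
        Sampling rate in Hz (96 000 in the reference measurement setup).
    channel : str
        Either ``"acoustic"`` (supraglottal microphone) or
        ``"subglottal"`` (tracheal pressure sensor).
    """

    samples: np.ndarray
    fs_hz: float
    channel: str = "acoustic"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be a 1-D array")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive")
        if self.channel not in ("acoustic", "subglottal"):
            raise ValueError(f"unknown channel {self.channel!r}")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs_hz

    @property
    def t(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.fs_hz


@dataclass
class GlottalAreaWaveform:
    """Total and left/right hemi glottal area versus time.

    Areas are non-negative; ``area_total`` equals ``area_left +
    area_right`` up to numeric precision (on-axis pixels are split
    half/half by the segmentation stage, so the identity is exact there).
    Units are mm^2 when a pixel scale is known, otherwise pixel^2.
    """

    area_total: np.ndarray
    fs_video_hz: float
    area_left: Optional[np.ndarray] = None
    area_right: Optional[np.ndarray] = None
    units: str = "mm^2"

    def __post_init__(self) -> None:
        self.area_total = np.asarray(self.area_total, dtype=float)
        if self.area_total.ndim != 1:
            raise ValueError("area_total must be 1-D")
        if self.fs_video_hz <= 0:
            raise ValueError("fs_video_hz must be positive")
        if np.any(self.area_total < -1e-9):
            raise ValueError("areas must be non-negative")
        for name in ("area_left", "area_right"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if v.shape != self.area_total.shape:
                    raise ValueError(f"{name} must match area_total shape")
                setattr(self, name, v)
        if self.area_left is not None and self.area_right is not None:
            s = self.area_left + self.area_right
            scale = max(1.0, float(np.max(self.area_total, initial=0.0)))
            if not np.allclose(s, self.area_total, atol=1e-6 * scale):
                raise ValueError("area_total must equal area_left + area_right")

    @property
    def has_hemi(self) -> bool:
        return self.area_left is not None and self.area_right is not None

    @property
    def t(self) -> np.ndarray:
        return np.arange(self.area_total.size) / self.fs_video_hz


@dataclass
class FrameStack:
    """High-speed video as a (time, height, width) intensity array."""

    frames: np.ndarray
    fs_video_hz: float
    pixel_scale_mm: Optional[float] = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a 3-D (time, height, width) array")
        if self.frames.shape[0] < 2:
            raise ValueError("a frame stack needs at least 2 frames")
        if self.fs_video_hz <= 0:
            raise ValueError("fs_video_hz must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple:
        return self.frames.shape
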