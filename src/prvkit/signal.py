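"""Core signal container shared by every pipeline stage."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import FormatError


@dataclass(frozen=True)
class BVPSignal:
    """A uniformly sampled blood-volume-pulse trace.

    Parameters
    ----------
    samples
        Amplitude series in arbitrary units (zero-mean after filtering).
    fs
        Sampling rate in Hz.
    t0
        Time of the first sample in seconds.
    """

    samples: np.ndarray
    fs: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if samples.ndim != 1 or samples.size < 2:
            raise FormatError("BVP signal must be a 1-D series of length >= 2")
        if not np.all(np.isfinite(samples)):
            raise FormatError("BVP signal contains non-finite values")
        if self.fs <= 0:
            raise FormatError(f"sampling rate must be positive, got {self.fs}")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        """Time span covered by the samples (first to last instant)."""
        return (len(self) - 1) / self.fs

    @property
    def times_s(self) -> np.ndarray:
        return self.t0 + np.arange(len(self)) / self.fs

    @property
    def times_ms(self) -> np.ndarray:
        return self.times_s * 1000.0


@dataclass(frozen=True)
class FrameSequence:
    """Ordered RGB frames, the raw camera-channel input.

    ``frames`` is an (N, H, W, 3) uint8 array; ``roi`` is an optional
    (x, y, w, h) rectangle in pixel coordinates (origin top-left) that
    restricts every downstream computation to a sub-window.
    """

    frames: np.ndarray
    fps: float
    roi: tuple[int, int, int, int] | None = field(default=None)

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames)
        object.__setattr__(self, "frames", frames)
        if frames.ndim != 4 or frames.shape[-1] != 3:
            raise FormatError(
                f"frames must be (N, H, W, 3) RGB, got shape {frames.shape}"
            )
        if self.fps <= 0:
            raise FormatError(f"fps must be positive, got {self.fps}")
        if self.roi is not None:
            x, y, w, h = self.roi
            _, fh, fw, _ = frames.shape
            if x < 0 or y < 0 or w <= 0 or h <= 0 or x + w > fw or y + h > fh:
                raise FormatError(f"roi {self.roi} outside {fw}x{fh} frame bounds")

    def __len__(self) -> int:
        return self.frames.shape[0]

    def crop_roi(self, frame: np.ndarray) -> np.ndarray:
        """Return the ROI window of one frame (the whole frame if no ROI)."""
        if self.roi is None:
            return frame
        x, y, w, h = self.roi
        return frame[y : y + h, x : x + w]
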