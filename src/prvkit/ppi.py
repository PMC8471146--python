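"""BVP -> inter-beat-interval pipeline.

A continuous BVP trace becomes a cleaned interval series in seven steps:
crop the unstable first/last 30 s, cut the remaining 10 min into eleven
overlapped 300 s segments (30 s hop), upsample the camera channel to the
contact rate (255 Hz) with a quadratic spline, bandpass to 0.5-2.0 Hz,
detect systolic peaks, difference peak times into peak-to-peak intervals
(PPI), and normalize the PPI to normal-to-normal intervals (NNI) by
replacing z-score outliers (|z| >= T, default T=2) with the median of
their immediate neighbors.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import make_interp_spline
from scipy.signal import find_peaks

from .errors import (
    EmptyResultError,
    ParameterError,
    SignalTooShortError,
)
from .rppg import bandpass_butterworth
from .signal import BVPSignal


@dataclass(frozen=True)
class SegmentSpec:
    """Cropping and overlapped-segmentation geometry (seconds).

    Defaults reproduce the study protocol: an 11 min recording cropped by
    30 s at each end leaves 10 min, which a 300 s window hopping by 30 s
    divides into exactly 11 overlapped segments.
    """

    window_s: float = 300.0
    stride_s: float = 30.0
    crop_head_s: float = 30.0
    crop_tail_s: float = 30.0

    def __post_init__(self) -> None:
        if self.window_s <= 0:
            raise ParameterError("window_s must be positive")
        if not 0 < self.stride_s <= self.window_s:
            raise ParameterError("need 0 < stride_s <= window_s")
        if self.crop_head_s < 0 or self.crop_tail_s < 0:
            raise ParameterError("crop lengths must be >= 0")


@dataclass(frozen=True)
class CleanConfig:
    """Resampling, filtering, peak-detection and outlier-rule settings."""

    z_threshold: float = 2.0
    fs_target: float = 255.0
    band: tuple[float, float] = (0.5, 2.0)
    min_peak_separation_s: float = 0.5  # a 2 Hz pulse allows no shorter interval

    def __post_init__(self) -> None:
        if self.z_threshold <= 0:
            raise ParameterError("z_threshold must be positive")
        if self.fs_target <= 2 * self.band[1]:
            raise ParameterError("fs_target must exceed twice the band ceiling")


@dataclass(frozen=True)
class PPISeries:
    """Detected beat times (ms) and their successive differences (ms)."""

    peak_times_ms: np.ndarray
    intervals_ms: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "peak_times_ms", np.asarray(self.peak_times_ms, dtype=float)
        )
        object.__setattr__(
            self, "intervals_ms", np.asarray(self.intervals_ms, dtype=float)
        )
        if self.intervals_ms.size != self.peak_times_ms.size - 1:
            raise ParameterError("intervals must be one shorter than peak times")
        if np.any(self.intervals_ms <= 0):
            raise ParameterError("peak times must be strictly increasing")


@dataclass(frozen=True)
class NNISeries:
    """Normalized intervals (ms) and the indices where outliers were replaced."""

    intervals_ms: np.ndarray
    replaced_indices: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "intervals_ms", np.asarray(self.intervals_ms, dtype=float)
        )
        object.__setattr__(
            self, "replaced_indices", np.asarray(self.replaced_indices, dtype=int)
        )
        if np.any(self.intervals_ms <= 0):
            raise ParameterError("intervals must be positive")


def crop_signal(bvp: BVPSignal, head_s: float, tail_s: float) -> BVPSignal:
    """Drop ``head_s`` seconds from the start and ``tail_s`` from the end."""
    n = len(bvp)
    i0 = int(round(head_s * bvp.fs))
    i1 = n - int(round(tail_s * bvp.fs))
    if i1 - i0 < 2:
        raise SignalTooShortError(
            f"signal of {n / bvp.fs:.1f} s cannot be cropped by {head_s}+{tail_s} s"
        )
    return BVPSignal(bvp.samples[i0:i1], fs=bvp.fs, t0=bvp.t0 + i0 / bvp.fs)


def segment_overlapped(bvp: BVPSignal, spec: SegmentSpec) -> list[BVPSignal]:
    """Cut into overlapped windows of ``window_s`` starting every ``stride_s``.

    Segment count is ``floor((n - window)/stride) + 1`` in samples; a signal
    exactly one window long yields one segment.
    """
    window_n = int(round(spec.window_s * bvp.fs))
    stride_n = max(1, int(round(spec.stride_s * bvp.fs)))
    n = len(bvp)
    if n < window_n:
        raise SignalTooShortError(
            f"{n / bvp.fs:.1f} s signal shorter than the {spec.window_s} s window"
        )
    count = (n - window_n) // stride_n + 1
    return [
        BVPSignal(
            bvp.samples[k * stride_n : k * stride_n + window_n],
            fs=bvp.fs,
            t0=bvp.t0 + (k * stride_n) / bvp.fs,
        )
        for k in range(count)
    ]


def resample_quadratic_spline(bvp: BVPSignal, fs_target: float) -> BVPSignal:
    """Upsample onto an ``fs_target`` grid with an order-2 interpolating spline.

    The spline passes through every original sample, so original instants
    reproduce original values and polynomials of degree <= 2 are preserved
    exactly.
    """
    if fs_target <= bvp.fs:
        raise ParameterError("fs_target must exceed the current sampling rate")
    if len(bvp) < 3:
        raise SignalTooShortError("need at least 3 samples for a quadratic spline")
    t = np.arange(len(bvp)) / bvp.fs
    spline = make_interp_spline(t, bvp.samples, k=2)
    m = int(np.floor(t[-1] * fs_target)) + 1
    t_new = np.arange(m) / fs_target
    return BVPSignal(spline(t_new), fs=fs_target, t0=bvp.t0)


def detect_peaks(bvp: BVPSignal, config: CleanConfig | None = None) -> np.ndarray:
    """Times (ms) of local maxima above zero, with a refractory period.

    Assumes a bandpassed (zero-mean) signal; the minimum separation rejects
    secondary wiggles faster than the band ceiling allows.
    """
    config = config or CleanConfig()
    distance = max(1, int(round(config.min_peak_separation_s * bvp.fs)))
    idx, _ = find_peaks(bvp.samples, height=0.0, distance=distance)
    if idx.size == 0:
        raise EmptyResultError("no peaks found")
    return (bvp.t0 + idx / bvp.fs) * 1000.0


def peaks_to_ppi(peak_times_ms: np.ndarray) -> PPISeries:
    """Difference successive peak times into peak-to-peak intervals."""
    times = np.asarray(peak_times_ms, dtype=float)
    if times.size < 2:
        raise SignalTooShortError("need at least 2 peaks for an interval")
    return PPISeries(times, np.diff(times))


def ppi_to_nni(ppi: PPISeries, config: CleanConfig | None = None) -> NNISeries:
    """Replace z-score outlier intervals with the median of their neighbors.

    z-scores use the mean and population standard deviation of the
    unmodified segment; intervals with |z| >= T are replaced, in index
    order, by the median of the immediately preceding and following
    interval values (their mean when both exist, the single neighbor at a
    boundary).  A zero-variance series has no definable outliers and is
    returned unchanged.
    """
    config = config or CleanConfig()
    x = ppi.intervals_ms
    if x.size < 3:
        raise SignalTooShortError("need at least 3 intervals")
    mean = x.mean()
    sd = x.std()  # population SD
    if sd == 0:
        return NNISeries(x.copy())
    z = (x - mean) / sd
    out = x.copy()
    replaced = []
    for i in np.flatnonzero(np.abs(z) >= config.z_threshold):
        neighbors = []
        if i > 0:
            neighbors.append(out[i - 1])
        if i < x.size - 1:
            neighbors.append(out[i + 1])
        out[i] = float(np.median(neighbors))
        replaced.append(int(i))
    return NNISeries(out, np.array(replaced, dtype=int))


def run_ppi_pipeline(
    bvp: BVPSignal,
    spec: SegmentSpec | None = None,
    config: CleanConfig | None = None,
) -> list[tuple[PPISeries, NNISeries]]:
    """Full chain: crop -> segment -> resample -> bandpass -> peaks -> PPI -> NNI.

    Resampling only runs when the input rate is below ``fs_target`` (the
    camera channel); the contact channel is already at the target rate.
    """
    spec = spec or SegmentSpec()
    config = config or CleanConfig()
    cropped = crop_signal(bvp, spec.crop_head_s, spec.crop_tail_s)
    results: list[tuple[PPISeries, NNISeries]] = []
    for segment in segment_overlapped(cropped, spec):
        if segment.fs < config.fs_target:
            segment = resample_quadratic_spline(segment, config.fs_target)
        filtered = replace(
            segment,
            samples=bandpass_butterworth(
                segment.samples, segment.fs, config.band[0], config.band[1]
            ),
        )
        peaks = detect_peaks(filtered, config)
        ppi = peaks_to_ppi(peaks)
        results.append((ppi, ppi_to_nni(ppi, config)))
    return results
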