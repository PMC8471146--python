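"""Chrominance-based remote photoplethysmography (rPPG).

Turns a sequence of RGB face/ROI frames into a single continuous blood
volume pulse (BVP) signal.  The heartbeat modulates the amount of light
absorbed by skin, producing tiny periodic shifts of skin chrominance; the
method isolates those shifts by

1. converting each frame to YCbCr (ITU-R BT.601, full range),
2. keeping pixels inside a configurable YCbCr skin-color box,
3. collapsing the skin pixels to their Cb-Cr cluster center,
4. randomly expanding the cluster around its center to stabilise the
   per-frame estimate against quantisation,
5. combining the Cb and Cr series into one BVP waveform,
6. removing the slow respiration baseline and band-pass filtering to the
   plausible pulse band (0.5-2.0 Hz, i.e. 30-120 bpm).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.signal import butter, filtfilt

from .errors import (
    DegenerateSignalError,
    ExtractionQualityError,
    FormatError,
    NoSkinError,
    ParameterError,
    SignalTooShortError,
)
from .signal import BVPSignal, FrameSequence

# BT.601 full-range ("JPEG") luma/chroma coefficients.
_KR, _KG, _KB = 0.299, 0.587, 0.114


@dataclass(frozen=True)
class SkinConfig:
    """Skin-color bounds (8-bit YCbCr) and cluster-expansion settings.

    The default box (Y >= 40, Cb in [77, 127], Cr in [133, 173]) is a widely
    used published YCbCr skin range; all bounds are user-configurable since
    skin tone, camera, and lighting shift the empirical range.
    """

    y_min: float = 40.0
    cb_min: float = 77.0
    cb_max: float = 127.0
    cr_min: float = 133.0
    cr_max: float = 173.0
    n_expansion: int = 100
    expansion_scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.cb_min < self.cb_max:
            raise ParameterError("cb_min must be < cb_max")
        if not self.cr_min < self.cr_max:
            raise ParameterError("cr_min must be < cr_max")
        if self.n_expansion < 1:
            raise ParameterError("n_expansion must be >= 1")
        if self.expansion_scale < 0:
            raise ParameterError("expansion_scale must be >= 0")


@dataclass(frozen=True)
class ChromaSample:
    """Per-frame chroma summary: cluster center and expanded-cluster mean."""

    t: float
    cb_center: float
    cr_center: float
    cb_expanded_mean: float
    cr_expanded_mean: float


def rgb_to_ycbcr(frame: np.ndarray) -> np.ndarray:
    """Convert an 8-bit RGB image to full-range YCbCr (BT.601).

    Returns a float array of the same spatial shape with channels
    (Y, Cb, Cr), each clipped to [0, 255].  Gray inputs map to
    (Y=gray, Cb=128, Cr=128).
    """
    frame = np.asarray(frame)
    if frame.ndim != 3 or frame.shape[-1] != 3:
        raise FormatError(f"expected an RGB image (H, W, 3), got shape {frame.shape}")
    r = frame[..., 0].astype(float)
    g = frame[..., 1].astype(float)
    b = frame[..., 2].astype(float)
    y = _KR * r + _KG * g + _KB * b
    cb = 128.0 + (b - y) * (0.5 / (1.0 - _KB))
    cr = 128.0 + (r - y) * (0.5 / (1.0 - _KR))
    return np.clip(np.stack([y, cb, cr], axis=-1), 0.0, 255.0)


def ycbcr_to_rgb(ycbcr: np.ndarray) -> np.ndarray:
    """Inverse of :func:`rgb_to_ycbcr`; returns uint8 RGB."""
    y = ycbcr[..., 0].astype(float)
    cb = ycbcr[..., 1].astype(float) - 128.0
    cr = ycbcr[..., 2].astype(float) - 128.0
    r = y + cr * (1.0 - _KR) / 0.5
    b = y + cb * (1.0 - _KB) / 0.5
    g = (y - _KR * r - _KB * b) / _KG
    rgb = np.stack([r, g, b], axis=-1)
    return np.clip(np.rint(rgb), 0, 255).astype(np.uint8)


def skin_mask(ycbcr_frame: np.ndarray, config: SkinConfig | None = None) -> np.ndarray:
    """Boolean mask of pixels inside the YCbCr skin-color box.

    Raises :class:`NoSkinError` when no pixel qualifies.
    """
    config = config or SkinConfig()
    y = ycbcr_frame[..., 0]
    cb = ycbcr_frame[..., 1]
    cr = ycbcr_frame[..., 2]
    mask = (
        (y >= config.y_min)
        & (cb >= config.cb_min)
        & (cb <= config.cb_max)
        & (cr >= config.cr_min)
        & (cr <= config.cr_max)
    )
    if not mask.any():
        raise NoSkinError("no pixels inside the skin-color bounds")
    return mask


def cluster_center(cb: np.ndarray, cr: np.ndarray) -> tuple[float, float]:
    """Centroid of skin-pixel (Cb, Cr) values on the chroma plane."""
    cb = np.asarray(cb, dtype=float).ravel()
    cr = np.asarray(cr, dtype=float).ravel()
    if cb.size == 0 or cb.size != cr.size:
        raise FormatError("cluster_center needs equal-length, non-empty Cb/Cr")
    return float(cb.mean()), float(cr.mean())


def random_expansion(
    center: tuple[float, float],
    config: SkinConfig,
    rng: np.random.Generator,
) -> tuple[float, float]:
    """Mean of ``n_expansion`` isotropic Gaussian draws around the center.

    The expansion emulates a denser skin-pixel cloud around the cluster
    center P(Cb-center, Cr-center); with ``expansion_scale=0`` it returns
    the center unchanged.  Deterministic given the generator state.
    """
    offsets = rng.normal(0.0, config.expansion_scale, size=(config.n_expansion, 2))
    cb = center[0] + offsets[:, 0].mean()
    cr = center[1] + offsets[:, 1].mean()
    return float(cb), float(cr)


def _constant(x: np.ndarray) -> bool:
    # ptp, not std: the mean of n identical floats is not bit-exact, which
    # makes std of a constant series ~1e-14 rather than 0
    return bool(np.ptp(x) == 0)


def _standardize(x: np.ndarray) -> np.ndarray:
    if _constant(x):
        return np.zeros_like(x)
    return (x - x.mean()) / x.std()


def chrominance_to_bvp(cb_series: np.ndarray, cr_series: np.ndarray) -> np.ndarray:
    """Combine Cb/Cr time series into a raw BVP waveform.

    The pulse raises Cr and lowers Cb, so the standardized difference
    Cr* - Cb* reinforces the pulse while cancelling common-mode drift.
    A constant channel contributes zero; if both channels are constant the
    frames carry no pulse and :class:`DegenerateSignalError` is raised.
    """
    cb = np.asarray(cb_series, dtype=float)
    cr = np.asarray(cr_series, dtype=float)
    if cb.shape != cr.shape or cb.ndim != 1 or cb.size < 2:
        raise FormatError("cb/cr series must be equal-length 1-D, length >= 2")
    if _constant(cb) and _constant(cr):
        raise DegenerateSignalError("both chroma channels are constant")
    bvp = _standardize(cr) - _standardize(cb)
    return bvp - bvp.mean()


def detrend_respiration(samples: np.ndarray, fs: float) -> np.ndarray:
    """Remove the slow breathing baseline by moving-average subtraction.

    The window spans ~1/0.4 s so content below about 0.4 Hz (respiration
    and illumination drift) is captured by the average and removed, while
    the >=0.5 Hz pulse band passes nearly untouched.
    """
    x = np.asarray(samples, dtype=float)
    window = int(round(fs / 0.4))
    if window < 1:
        raise ParameterError("sampling rate too low for the detrend window")
    if x.size <= window:
        raise SignalTooShortError(
            f"signal of {x.size} samples shorter than detrend window {window}"
        )
    baseline = uniform_filter1d(x, size=window, mode="nearest")
    out = x - baseline
    return out - out.mean()


def bandpass_butterworth(
    samples: np.ndarray,
    fs: float,
    f_lo: float,
    f_hi: float,
    order: int = 4,
) -> np.ndarray:
    """Zero-phase Butterworth bandpass (forward-backward application)."""
    if not 0 < f_lo < f_hi:
        raise ParameterError(f"need 0 < f_lo < f_hi, got ({f_lo}, {f_hi})")
    if f_hi >= fs / 2:
        raise ParameterError(f"f_hi={f_hi} must be below the Nyquist rate {fs / 2}")
    b, a = butter(order, [f_lo, f_hi], btype="bandpass", fs=fs)
    return filtfilt(b, a, np.asarray(samples, dtype=float))


def chroma_series(
    frames: FrameSequence, config: SkinConfig | None = None
) -> list[ChromaSample | None]:
    """Per-frame chroma samples; ``None`` marks frames without skin."""
    config = config or SkinConfig()
    rng = np.random.default_rng(config.seed)
    out: list[ChromaSample | None] = []
    for i in range(len(frames)):
        t = i / frames.fps
        ycbcr = rgb_to_ycbcr(frames.crop_roi(frames.frames[i]))
        try:
            mask = skin_mask(ycbcr, config)
        except NoSkinError:
            # keep the generator stream aligned so missing frames do not
            # shift the expansion draws of later frames
            rng.normal(0.0, config.expansion_scale, size=(config.n_expansion, 2))
            out.append(None)
            continue
        center = cluster_center(ycbcr[..., 1][mask], ycbcr[..., 2][mask])
        cb_exp, cr_exp = random_expansion(center, config, rng)
        out.append(ChromaSample(t, center[0], center[1], cb_exp, cr_exp))
    return out


def extract_bvp(frames: FrameSequence, config: SkinConfig | None = None) -> BVPSignal:
    """Full camera-to-BVP chain.

    Composes YCbCr conversion, skin masking, Cb-Cr clustering, random
    expansion, chrominance combination, respiration detrending and a
    0.5-2.0 Hz zero-phase bandpass.  Frames with no detectable skin are
    filled by linear interpolation of neighboring chroma samples; if more
    than 10% of frames lack skin the extraction is rejected.
    """
    config = config or SkinConfig()
    if len(frames) < 2:
        raise SignalTooShortError("need at least 2 frames")
    samples = chroma_series(frames, config)
    missing = np.array([s is None for s in samples])
    if missing.mean() > 0.10:
        raise ExtractionQualityError(
            f"{missing.sum()}/{len(samples)} frames without detectable skin"
        )
    if missing.all():
        raise ExtractionQualityError("no frame contains detectable skin")
    idx = np.arange(len(samples), dtype=float)
    good = ~missing
    # degeneracy is judged on the cluster centers: the random expansion adds
    # jitter, so a static scene would otherwise look (spuriously) modulated
    cb_center = np.array([s.cb_center for s in samples if s])
    cr_center = np.array([s.cr_center for s in samples if s])
    if _constant(cb_center) and _constant(cr_center):
        raise DegenerateSignalError("static chrominance: frames carry no pulse")
    cb = np.array([s.cb_expanded_mean if s else np.nan for s in samples])
    cr = np.array([s.cr_expanded_mean if s else np.nan for s in samples])
    if missing.any():
        cb[missing] = np.interp(idx[missing], idx[good], cb[good])
        cr[missing] = np.interp(idx[missing], idx[good], cr[good])
    raw = chrominance_to_bvp(cb, cr)
    detrended = detrend_respiration(raw, frames.fps)
    filtered = bandpass_butterworth(detrended, frames.fps, 0.5, 2.0)
    return BVPSignal(filtered, fs=frames.fps, t0=0.0)
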