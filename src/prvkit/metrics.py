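"""Time- and frequency-domain pulse rate variability indices.

Five indicators summarise one NNI segment: mean NN and SDNN in the time
domain; LFnu, HFnu and LF/HF in the frequency domain.  Spectral indices
come from the interval tachogram (interval value vs cumulative beat time),
resampled to a uniform 4 Hz grid with a quadratic spline and analysed with
Welch's averaged-periodogram PSD.  Normalized units divide the LF or HF
band power by (total - VLF) power:

    LFnu [%] = 100 * LF / (total - VLF),   HFnu [%] = 100 * HF / (total - VLF)

with total power taken as the VLF+LF+HF integral (0.0033-0.4 Hz), so
LFnu + HFnu = 100 by construction.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
from scipy.interpolate import make_interp_spline
from scipy.signal import welch

from .errors import (
    DegenerateSpectrumError,
    ParameterError,
    SignalTooShortError,
)
from .ppi import NNISeries, PPISeries


@dataclass(frozen=True)
class BandDefinition:
    """Spectral band edges in Hz (VLF / LF / HF, non-overlapping, ordered)."""

    vlf: tuple[float, float] = (0.0033, 0.04)
    lf: tuple[float, float] = (0.04, 0.15)
    hf: tuple[float, float] = (0.15, 0.4)

    def __post_init__(self) -> None:
        edges = [*self.vlf, *self.lf, *self.hf]
        if any(b[0] >= b[1] for b in (self.vlf, self.lf, self.hf)):
            raise ParameterError("each band needs f_lo < f_hi")
        if edges != sorted(edges):
            raise ParameterError("bands must be ordered VLF < LF < HF")


@dataclass(frozen=True)
class SpectralConfig:
    """Tachogram resampling rate and Welch averaging-window settings."""

    resample_hz: float = 4.0
    psd_window_s: float = 120.0
    psd_overlap_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.resample_hz <= 0.8:  # must resolve the 0.4 Hz band ceiling
            raise ParameterError("resample_hz must exceed twice the HF ceiling")
        if not 0 <= self.psd_overlap_fraction < 1:
            raise ParameterError("psd_overlap_fraction must be in [0, 1)")


@dataclass(frozen=True)
class PRVIndices:
    """The five PRV indicators plus the band powers behind them."""

    mean_nn: float  # ms
    sdnn: float  # ms
    vlf_power: float  # ms^2
    lf_power: float  # ms^2
    hf_power: float  # ms^2
    total_power: float  # ms^2
    lfnu: float  # %
    hfnu: float  # %
    lf_hf: float  # dimensionless

    def as_dict(self) -> dict[str, float]:
        return asdict(self)


def _intervals(nni: NNISeries | PPISeries | np.ndarray) -> np.ndarray:
    if isinstance(nni, (NNISeries, PPISeries)):
        return nni.intervals_ms
    return np.asarray(nni, dtype=float)


def mean_nn(nni: NNISeries | np.ndarray) -> float:
    """Arithmetic mean of the intervals, in ms."""
    x = _intervals(nni)
    if x.size == 0:
        raise SignalTooShortError("empty interval series")
    return float(x.mean())


def sdnn(nni: NNISeries | np.ndarray) -> float:
    """Population standard deviation of the intervals, in ms."""
    x = _intervals(nni)
    if x.size < 2:
        raise SignalTooShortError("need at least 2 intervals")
    return float(x.std())


def tachogram_psd(
    nni: NNISeries | np.ndarray,
    cfg: SpectralConfig | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """One-sided PSD (ms^2/Hz) of the uniformly resampled interval tachogram.

    The tachogram places interval i at its ending beat time (cumulative sum
    of intervals); a quadratic spline resamples it to ``resample_hz``, the
    mean is removed, and Welch's method with Hann windows of
    ``psd_window_s`` (50% overlap by default) estimates the density.
    """
    cfg = cfg or SpectralConfig()
    x = _intervals(nni)
    if x.size < 4:
        raise SignalTooShortError("need at least 4 intervals for a spectrum")
    t_beat = np.cumsum(x) / 1000.0  # s
    span = t_beat[-1] - t_beat[0]
    if span < 2 / 0.04:
        raise SignalTooShortError(
            f"tachogram spans {span:.0f} s; need >= {2 / 0.04:.0f} s of beats"
        )
    spline = make_interp_spline(t_beat, x, k=2)
    n_uniform = int(np.floor(span * cfg.resample_hz)) + 1
    uniform = spline(t_beat[0] + np.arange(n_uniform) / cfg.resample_hz)
    uniform = uniform - uniform.mean()
    nperseg = min(n_uniform, int(round(cfg.psd_window_s * cfg.resample_hz)))
    freqs, psd = welch(
        uniform,
        fs=cfg.resample_hz,
        window="hann",
        nperseg=nperseg,
        noverlap=int(nperseg * cfg.psd_overlap_fraction),
        detrend="constant",
    )
    return freqs, psd


def band_power(
    freqs: np.ndarray, psd: np.ndarray, band: tuple[float, float]
) -> float:
    """Trapezoidal integral of the density over [f_lo, f_hi), in ms^2.

    Band edges falling between grid points are handled by linear
    interpolation of the density at the exact edges.
    """
    f_lo, f_hi = band
    if f_lo < freqs[0] or f_hi > freqs[-1]:
        raise ParameterError(
            f"band ({f_lo}, {f_hi}) outside PSD support "
            f"({freqs[0]:.4g}, {freqs[-1]:.4g})"
        )
    inner = (freqs > f_lo) & (freqs < f_hi)
    f = np.concatenate(([f_lo], freqs[inner], [f_hi]))
    p = np.concatenate(
        ([np.interp(f_lo, freqs, psd)], psd[inner], [np.interp(f_hi, freqs, psd)])
    )
    return float(np.trapezoid(p, f))


def normalized_units(
    lf_power: float, hf_power: float, vlf_power: float, total_power: float
) -> tuple[float, float]:
    """LFnu and HFnu in percent: band power over (total - VLF) power."""
    denom = total_power - vlf_power
    if denom <= 0:
        raise DegenerateSpectrumError("no power outside the VLF band")
    return 100.0 * lf_power / denom, 100.0 * hf_power / denom


def compute_prv(
    nni: NNISeries | np.ndarray,
    bands: BandDefinition | None = None,
    cfg: SpectralConfig | None = None,
) -> PRVIndices:
    """All five PRV indicators for one (nominally 300 s) interval segment."""
    bands = bands or BandDefinition()
    cfg = cfg or SpectralConfig()
    if np.ptp(_intervals(nni)) == 0:
        raise DegenerateSpectrumError(
            "constant interval series has no spectral content"
        )
    freqs, psd = tachogram_psd(nni, cfg)
    vlf = band_power(freqs, psd, bands.vlf)
    lf = band_power(freqs, psd, bands.lf)
    hf = band_power(freqs, psd, bands.hf)
    total = vlf + lf + hf
    lfnu, hfnu = normalized_units(lf, hf, vlf, total)
    if hf == 0:
        raise DegenerateSpectrumError("HF power is zero; LF/HF undefined")
    return PRVIndices(
        mean_nn=mean_nn(nni),
        sdnn=sdnn(nni),
        vlf_power=vlf,
        lf_power=lf,
        hf_power=hf,
        total_power=total,
        lfnu=lfnu,
        hfnu=hfnu,
        lf_hf=lf / hf,
    )
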