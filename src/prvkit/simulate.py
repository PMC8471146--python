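"""Synthetic paired recordings with known ground truth.

The study conditions this package analyses — paired 11 min contact
(255 Hz) and camera (30 Hz) recordings of the same heart-beat process,
with autonomic LF/HF interval modulation and sporadic camera-side motion
artifacts — come from human subjects whose data are not shareable.  This
module generates statistically equivalent inputs from an integral pulse
frequency modulation (IPFM) model:

    r(t) = (mean_rate_bpm / 60) * (1 + a_LF sin(2*pi*f_LF t)
                                     + a_HF sin(2*pi*f_HF t))

with beats at the integer crossings of the integrated rate.  Beat trains
are rendered to BVP traces as Gaussian pulse templates plus white channel
noise, and skin-colored video frames whose chrominance follows the pulse
waveform exercise the camera-extraction path.  Every generator is
deterministic given its seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .errors import ParameterError
from .rppg import SkinConfig, ycbcr_to_rgb
from .signal import BVPSignal, FrameSequence


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition parameters for one simulated subject.

    Defaults emulate the benchmark protocol: 11 min recordings, contact
    channel at 255 Hz, camera at 30 Hz, resting-adult heart rate, LF/HF
    modulation at mid-band frequencies with a few percent depth (giving
    SDNN of a few tens of ms), and occasional camera-side motion
    artifacts that displace individual beats.
    """

    duration_s: float = 660.0
    mean_rate_bpm: float = 75.0
    lf_freq_hz: float = 0.10
    lf_depth: float = 0.06
    hf_freq_hz: float = 0.30
    hf_depth: float = 0.04
    artifact_rate_per_min: float = 2.0
    artifact_magnitude: float = 0.35
    channel_noise_sd: float = 0.1
    fs_contact: float = 255.0
    fs_camera: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.04 < self.lf_freq_hz < 0.15 < self.hf_freq_hz < 0.4:
            raise ParameterError("modulation frequencies must sit in the LF/HF bands")
        if not (0 <= self.lf_depth < 0.5 and 0 <= self.hf_depth < 0.5):
            raise ParameterError("modulation depths must lie in [0, 0.5)")
        if self.lf_depth + self.hf_depth >= 1:
            raise ParameterError("combined depth drives the rate non-positive")
        if self.duration_s < 360:
            raise ParameterError("duration_s must be >= 360 s")
        if self.mean_rate_bpm <= 0:
            raise ParameterError("mean_rate_bpm must be positive")
        if self.artifact_rate_per_min < 0 or not 0 <= self.artifact_magnitude < 1:
            raise ParameterError("invalid artifact settings")


@dataclass(frozen=True)
class GroundTruth:
    """Beat times and intervals of one simulated channel, with provenance."""

    beat_times_ms: np.ndarray
    true_nni_ms: np.ndarray
    artifact_indices: np.ndarray = field(
        default_factory=lambda: np.array([], dtype=int)
    )
    lf_depth: float = 0.0
    hf_depth: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "beat_times_ms", np.asarray(self.beat_times_ms, dtype=float)
        )
        object.__setattr__(
            self, "true_nni_ms", np.asarray(self.true_nni_ms, dtype=float)
        )
        object.__setattr__(
            self, "artifact_indices", np.asarray(self.artifact_indices, dtype=int)
        )
        if np.any(np.diff(self.beat_times_ms) <= 0):
            raise ParameterError("beat times must be strictly increasing")


@dataclass(frozen=True)
class DualGroundTruth:
    """Clean beat process plus the artifact-perturbed camera-channel view."""

    contact: GroundTruth
    camera: GroundTruth


def simulate_beats(cfg: SimulationConfig) -> GroundTruth:
    """IPFM beat times: integer crossings of the integrated modulated rate.

    The rate integral has the closed form

        I(t) = f0 * (t + a_LF/w_LF (1 - cos w_LF t) + a_HF/w_HF (1 - cos w_HF t))

    (w = 2*pi*f); beat k solves I(t) = k, found by bisection to 0.1 ms.
    A beat is emitted at t = 0 (I = 0).
    """
    f0 = cfg.mean_rate_bpm / 60.0
    w_lf = 2 * np.pi * cfg.lf_freq_hz
    w_hf = 2 * np.pi * cfg.hf_freq_hz

    def integral(t: float) -> float:
        return f0 * (
            t
            + cfg.lf_depth / w_lf * (1 - np.cos(w_lf * t))
            + cfg.hf_depth / w_hf * (1 - np.cos(w_hf * t))
        )

    n_beats = int(np.floor(integral(cfg.duration_s)))
    max_interval = 1.0 / (f0 * (1 - cfg.lf_depth - cfg.hf_depth))
    times = np.empty(n_beats + 1)
    times[0] = 0.0
    for k in range(1, n_beats + 1):
        lo = times[k - 1]
        hi = lo + 1.5 * max_interval
        while integral(hi) < k:  # pragma: no cover - bracket is generous
            hi += max_interval
        times[k] = brentq(lambda t: integral(t) - k, lo, hi, xtol=1e-5)
    beat_ms = times * 1000.0
    return GroundTruth(
        beat_ms, np.diff(beat_ms), lf_depth=cfg.lf_depth, hf_depth=cfg.hf_depth
    )


def inject_artifacts(
    truth: GroundTruth,
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> GroundTruth:
    """Displace randomly chosen beats, producing outlier interval pairs.

    Artifact epochs are Poisson-placed at ``artifact_rate_per_min``; each
    shifts one interior beat by +-``artifact_magnitude`` times the local
    interval, shortening one adjacent interval and lengthening the other
    (the signature of a mis-detected peak under motion).  Displaced beat
    indices are recorded.
    """
    if cfg.artifact_rate_per_min == 0:
        return truth
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    beats = truth.beat_times_ms.copy()
    n_interior = beats.size - 2
    n_art = min(int(rng.poisson(cfg.artifact_rate_per_min * cfg.duration_s / 60.0)),
                n_interior)
    if n_art == 0:
        return truth
    indices = np.sort(rng.choice(np.arange(1, beats.size - 1), n_art, replace=False))
    signs = rng.choice([-1.0, 1.0], size=n_art)
    for i, s in zip(indices, signs):
        local = min(beats[i] - beats[i - 1], beats[i + 1] - beats[i])
        beats[i] += s * cfg.artifact_magnitude * local
    return GroundTruth(
        beats,
        np.diff(beats),
        artifact_indices=indices,
        lf_depth=truth.lf_depth,
        hf_depth=truth.hf_depth,
    )


def beats_to_bvp(
    truth: GroundTruth,
    fs: float,
    pulse_width_s: float = 0.12,
    noise_sd: float = 0.0,
    seed: int = 0,
    duration_s: float | None = None,
) -> BVPSignal:
    """Render a beat train as a BVP trace: one Gaussian pulse per beat.

    ``pulse_width_s`` is the full width at half maximum of the unit-height
    template; white Gaussian noise of ``noise_sd`` (amplitude units) is
    added on the uniform grid.  The grid spans ``duration_s`` when given
    (the recording length), otherwise up to the last beat.  Warns when
    pulses overlap the shortest interval.
    """
    beat_s = truth.beat_times_ms / 1000.0
    min_nni_s = np.diff(beat_s).min() if beat_s.size > 1 else np.inf
    if pulse_width_s >= min_nni_s:
        warnings.warn(
            f"pulse width {pulse_width_s}s >= minimum interval {min_nni_s:.3f}s; "
            "pulses overlap",
            stacklevel=2,
        )
    sigma = pulse_width_s / (2 * np.sqrt(2 * np.log(2)))  # FWHM -> SD
    span = duration_s if duration_s is not None else beat_s[-1]
    n = int(round(span * fs))
    t = np.arange(n) / fs
    x = np.zeros(n)
    half = 5 * sigma
    for tb in beat_s:
        i0 = max(0, int(np.ceil((tb - half) * fs)))
        i1 = min(n, int(np.floor((tb + half) * fs)) + 1)
        x[i0:i1] += np.exp(-0.5 * ((t[i0:i1] - tb) / sigma) ** 2)
    if noise_sd > 0:
        x = x + np.random.default_rng(seed).normal(0.0, noise_sd, size=n)
    return BVPSignal(x, fs=fs, t0=0.0)


def simulate_dual_recording(
    cfg: SimulationConfig,
) -> tuple[BVPSignal, BVPSignal, DualGroundTruth]:
    """One beat process observed by both channels.

    The contact channel renders the clean beats; the camera channel
    renders artifact-perturbed beats (motion affects only the camera) at
    its lower rate, with independent channel noise.
    """
    seeds = np.random.SeedSequence(cfg.seed).generate_state(3)
    clean = simulate_beats(cfg)
    perturbed = inject_artifacts(clean, cfg, np.random.default_rng(int(seeds[0])))
    contact = beats_to_bvp(
        clean,
        cfg.fs_contact,
        noise_sd=cfg.channel_noise_sd,
        seed=int(seeds[1]),
        duration_s=cfg.duration_s,
    )
    camera = beats_to_bvp(
        perturbed,
        cfg.fs_camera,
        noise_sd=cfg.channel_noise_sd,
        seed=int(seeds[2]),
        duration_s=cfg.duration_s,
    )
    return contact, camera, DualGroundTruth(contact=clean, camera=perturbed)


# Skin base color (YCbCr), an interior point of the default SkinConfig box.
_SKIN_YCBCR = (140.0, 105.0, 155.0)
_BACKGROUND_RGB = (0, 0, 255)  # blue: far outside any skin-color range


def simulate_face_frames(
    truth: GroundTruth,
    fps: float = 30.0,
    size: tuple[int, int] = (48, 48),
    skin_fraction: float = 1.0,
    modulation_depth: float = 2.0,
    seed: int = 0,
    pixel_noise_sd: float = 0.0,
) -> FrameSequence:
    """Video frames whose skin-region chrominance follows the pulse.

    The top ``skin_fraction`` of rows is skin-colored; its Cr rises and Cb
    falls by ``modulation_depth`` (8-bit channel units) times the rendered
    pulse waveform, mimicking the optical effect of blood volume on skin
    color.  The rest is a static blue background.  Optional per-pixel
    Gaussian noise (``pixel_noise_sd``) emulates sensor noise.
    """
    if not 0 < skin_fraction <= 1:
        raise ParameterError("skin_fraction must be in (0, 1]")
    if modulation_depth < 0 or modulation_depth > 5:
        raise ParameterError("modulation_depth must be in [0, 5] channel units")
    pulse = beats_to_bvp(truth, fps).samples
    peak = np.abs(pulse).max()
    if peak > 0:
        pulse = pulse / peak  # unit peak; modulation_depth sets the swing
    h, w = size
    skin_rows = max(1, int(round(h * skin_fraction)))
    rng = np.random.default_rng(seed)
    y0, cb0, cr0 = _SKIN_YCBCR
    frames = np.empty((pulse.size, h, w, 3), dtype=np.uint8)
    for i, p in enumerate(pulse):
        ycbcr = np.empty((h, w, 3))
        ycbcr[..., 0] = y0
        ycbcr[..., 1] = cb0 - modulation_depth * p
        ycbcr[..., 2] = cr0 + modulation_depth * p
        if pixel_noise_sd > 0:
            ycbcr += rng.normal(0.0, pixel_noise_sd, size=ycbcr.shape)
        frame = ycbcr_to_rgb(np.clip(ycbcr, 0, 255))
        frame[skin_rows:, :, :] = _BACKGROUND_RGB
        frames[i] = frame
    return FrameSequence(frames, fps=fps)


def default_skin_config(seed: int = 0) -> SkinConfig:
    """Skin config matching the simulated frames' color box."""
    return SkinConfig(seed=seed)
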