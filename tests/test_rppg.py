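"""Chrominance extraction: color transform, skin masking, BVP recovery."""

import numpy as np
import pytest

import prvkit as pk
from prvkit.errors import (
    DegenerateSignalError,
    NoSkinError,
    ParameterError,
    SignalTooShortError,
)
from prvkit.rppg import chroma_series, random_expansion, ycbcr_to_rgb
from prvkit.simulate import simulate_face_frames


def bt601_scalar(r, g, b):
    """Independent scalar BT.601 full-range transform (published coefficients)."""
    y = 0.299 * r + 0.587 * g + 0.114 * b
    cb = 128.0 - 0.168736 * r - 0.331264 * g + 0.5 * b
    cr = 128.0 + 0.5 * r - 0.418688 * g - 0.081312 * b
    return y, cb, cr


class TestColorTransform:
    def test_achromatic_fixed_point(self):
        frame = np.full((4, 4, 3), 128, dtype=np.uint8)
        out = pk.rgb_to_ycbcr(frame)
        assert np.allclose(out[..., 0], 128) and np.allclose(out[..., 1:], 128)

    def test_black(self):
        out = pk.rgb_to_ycbcr(np.zeros((2, 2, 3), dtype=np.uint8))
        assert np.allclose(out[..., 0], 0) and np.allclose(out[..., 1:], 128)

    @pytest.mark.parametrize(
        "rgb", [(255, 0, 0), (0, 255, 0), (0, 0, 255), (10, 200, 77), (255, 255, 0)]
    )
    def test_matches_scalar_oracle(self, rgb):
        frame = np.array(rgb, dtype=np.uint8).reshape(1, 1, 3)
        got = pk.rgb_to_ycbcr(frame)[0, 0]
        expected = np.clip(bt601_scalar(*map(float, rgb)), 0, 255)
        assert np.allclose(got, expected, atol=1e-9)

    def test_rejects_non_rgb(self):
        with pytest.raises(pk.PRVError):
            pk.rgb_to_ycbcr(np.zeros((4, 4), dtype=np.uint8))

    def test_round_trip_within_quantization(self):
        rng = np.random.default_rng(0)
        frame = rng.integers(0, 256, size=(8, 8, 3), dtype=np.uint8)
        back = ycbcr_to_rgb(pk.rgb_to_ycbcr(frame))
        assert np.max(np.abs(back.astype(int) - frame.astype(int))) <= 1


class TestSkinMask:
    def _frame(self, y, cb, cr, shape=(4, 4)):
        out = np.empty((*shape, 3))
        out[..., 0], out[..., 1], out[..., 2] = y, cb, cr
        return out

    def test_interior_point_all_true(self):
        assert pk.skin_mask(self._frame(150, 110, 150)).all()

    def test_no_skin_raises(self):
        with pytest.raises(NoSkinError):
            pk.skin_mask(self._frame(150, 0, 0))

    def test_half_skin_half_blue(self):
        frame = self._frame(150, 110, 150, shape=(4, 4))
        blue = pk.rgb_to_ycbcr(np.broadcast_to([0, 0, 255], (2, 4, 3)).astype(np.uint8))
        frame[2:] = blue
        mask = pk.skin_mask(frame)
        assert mask[:2].all() and not mask[2:].any()

    def test_matches_bound_predicate_on_random_frames(self):
        cfg = pk.SkinConfig()
        rng = np.random.default_rng(42)
        frame = rng.uniform(0, 255, size=(16, 16, 3))
        # guarantee at least one skin pixel
        frame[0, 0] = (150, 110, 150)
        mask = pk.skin_mask(frame, cfg)
        y, cb, cr = frame[..., 0], frame[..., 1], frame[..., 2]
        oracle = (
            (y >= cfg.y_min)
            & (cb >= cfg.cb_min) & (cb <= cfg.cb_max)
            & (cr >= cfg.cr_min) & (cr <= cfg.cr_max)
        )
        assert np.array_equal(mask, oracle)
        assert np.array_equal(pk.skin_mask(frame, cfg), mask)  # idempotent


class TestClusterAndExpansion:
    def test_single_pixel_identity(self):
        assert pk.cluster_center([100.0], [150.0]) == (100.0, 150.0)

    def test_mean_of_two(self):
        assert pk.cluster_center([100, 102], [150, 152]) == (101.0, 151.0)

    def test_centroid_matches_distribution_mean(self):
        rng = np.random.default_rng(7)
        cb = rng.normal(105, 3, size=1000)
        cr = rng.normal(155, 3, size=1000)
        center = pk.cluster_center(cb, cr)
        assert abs(center[0] - 105) < 0.5 and abs(center[1] - 155) < 0.5

    def test_zero_scale_returns_center(self):
        cfg = pk.SkinConfig(expansion_scale=0.0, n_expansion=10)
        rng = np.random.default_rng(0)
        assert random_expansion((105.0, 155.0), cfg, rng) == (105.0, 155.0)

    def test_deterministic_given_seed(self):
        cfg = pk.SkinConfig(n_expansion=100, expansion_scale=1.0)
        a = random_expansion((105, 155), cfg, np.random.default_rng(5))
        b = random_expansion((105, 155), cfg, np.random.default_rng(5))
        assert a == b

    def test_converges_to_center(self):
        cfg = pk.SkinConfig(n_expansion=10_000, expansion_scale=1.0)
        cb, cr = random_expansion((105, 155), cfg, np.random.default_rng(11))
        bound = 3 * cfg.expansion_scale / np.sqrt(cfg.n_expansion)
        assert abs(cb - 105) < bound and abs(cr - 155) < bound


class TestChrominanceToBVP:
    def test_constant_cb_passes_cr(self):
        t = np.linspace(0, 10, 300)
        cr = np.sin(2 * np.pi * t)
        bvp = pk.chrominance_to_bvp(np.full_like(cr, 105.0), cr)
        assert abs(bvp.mean()) < 1e-12
        r = np.corrcoef(bvp, cr)[0, 1]
        assert abs(r) > 0.999

    def test_identical_channels_cancel(self):
        x = np.sin(np.linspace(0, 20, 200)) + 100
        assert np.allclose(pk.chrominance_to_bvp(x, x), 0.0)

    def test_antiphase_doubles_amplitude(self):
        t = np.linspace(0, 10, 1000, endpoint=False)
        s = np.sin(2 * np.pi * t)
        combined = pk.chrominance_to_bvp(-s, s)
        single = pk.chrominance_to_bvp(np.zeros_like(s), s)
        assert np.allclose(combined, 2 * single, atol=1e-9)

    def test_both_constant_degenerate(self):
        with pytest.raises(DegenerateSignalError):
            pk.chrominance_to_bvp(np.full(10, 1.0), np.full(10, 2.0))


class TestDetrendAndBandpass:
    @staticmethod
    def _power(x):
        return float(np.mean(np.square(x)))

    def test_removes_slow_trend(self):
        fs = 30.0
        t = np.arange(0, 60, 1 / fs)
        x = np.sin(2 * np.pi * 0.05 * t)
        out = pk.detrend_respiration(x, fs)
        assert self._power(out) < 0.1 * self._power(x)

    def test_preserves_pulse_band(self):
        fs = 30.0
        t = np.arange(0, 60, 1 / fs)
        x = np.sin(2 * np.pi * 1.2 * t)
        out = pk.detrend_respiration(x, fs)
        assert self._power(out) >= 0.9 * self._power(x)

    def test_constant_maps_to_zero(self):
        assert np.allclose(pk.detrend_respiration(np.full(500, 3.3), 30.0), 0.0)

    def test_too_short_raises(self):
        with pytest.raises(SignalTooShortError):
            pk.detrend_respiration(np.ones(10), 30.0)

    @pytest.mark.parametrize(
        "freq,lo,hi", [(1.0, 0.95, 1.05), (5.0, 0.0, 0.10)]
    )
    def test_bandpass_amplitude(self, freq, lo, hi):
        fs = 30.0
        t = np.arange(0, 60, 1 / fs)
        x = np.sin(2 * np.pi * freq * t)
        out = pk.bandpass_butterworth(x, fs, 0.5, 2.0)
        # measure away from filtfilt edge transients
        core = slice(len(t) // 4, 3 * len(t) // 4)
        ratio = np.abs(out[core]).max() / np.abs(x[core]).max()
        assert lo <= ratio <= hi

    def test_zero_in_zero_out(self):
        assert np.allclose(pk.bandpass_butterworth(np.zeros(1000), 30, 0.5, 2.0), 0.0)

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(ParameterError):
            pk.bandpass_butterworth(np.zeros(100), 30, 0.5, 16.0)


class TestExtractBVP:
    @pytest.mark.parametrize("rate_bpm", [42.0, 60.0, 84.0, 108.0])
    def test_recovers_pulse_frequency(self, rate_bpm):
        cfg = pk.SimulationConfig(
            duration_s=660, mean_rate_bpm=rate_bpm, lf_depth=0.0, hf_depth=0.0,
            artifact_rate_per_min=0.0,
        )
        truth = pk.simulate_beats(cfg)
        keep = truth.beat_times_ms <= 60_000
        short = pk.GroundTruth(truth.beat_times_ms[keep], np.diff(truth.beat_times_ms[keep]))
        frames = simulate_face_frames(short, fps=30.0, modulation_depth=2.0, seed=3)
        bvp = pk.extract_bvp(frames, pk.SkinConfig(seed=7))
        f = np.fft.rfftfreq(len(bvp), 1 / bvp.fs)
        peak = f[np.argmax(np.abs(np.fft.rfft(bvp.samples)) ** 2)]
        assert abs(peak - rate_bpm / 60.0) <= f[1]  # within one spectral bin

    def test_background_permutation_invariance(self, short_constant_beats):
        frames = simulate_face_frames(
            short_constant_beats, fps=30.0, skin_fraction=0.5, seed=3
        )
        bvp = pk.extract_bvp(frames, pk.SkinConfig(seed=7))
        shuffled = frames.frames.copy()
        rng = np.random.default_rng(99)
        h = shuffled.shape[1]
        bg = shuffled[:, h // 2 :, :, :]
        shuffled[:, h // 2 :, :, :] = rng.permutation(bg.reshape(len(frames), -1, 3), axis=1).reshape(bg.shape)
        bvp2 = pk.extract_bvp(
            pk.FrameSequence(shuffled, fps=30.0), pk.SkinConfig(seed=7)
        )
        assert np.array_equal(bvp.samples, bvp2.samples)

    def test_bit_reproducible(self, short_constant_beats):
        frames = simulate_face_frames(short_constant_beats, fps=30.0, seed=3)
        a = pk.extract_bvp(frames, pk.SkinConfig(seed=7))
        b = pk.extract_bvp(frames, pk.SkinConfig(seed=7))
        assert np.array_equal(a.samples, b.samples)

    def test_static_frames_degenerate(self, short_constant_beats):
        frames = simulate_face_frames(
            short_constant_beats, fps=30.0, modulation_depth=0.0, seed=3
        )
        with pytest.raises(DegenerateSignalError):
            pk.extract_bvp(frames, pk.SkinConfig(seed=7))

    def test_too_many_skinless_frames_rejected(self, short_constant_beats):
        frames = simulate_face_frames(short_constant_beats, fps=30.0, seed=3)
        arr = frames.frames.copy()
        arr[: int(0.2 * len(frames))] = (0, 0, 255)  # 20% pure-blue frames
        with pytest.raises(pk.PRVError):
            pk.extract_bvp(pk.FrameSequence(arr, fps=30.0), pk.SkinConfig(seed=7))

    def test_sparse_skinless_frames_interpolated(self, short_constant_beats):
        frames = simulate_face_frames(short_constant_beats, fps=30.0, seed=3)
        arr = frames.frames.copy()
        arr[100] = (0, 0, 255)
        arr[700] = (0, 0, 255)
        bvp = pk.extract_bvp(pk.FrameSequence(arr, fps=30.0), pk.SkinConfig(seed=7))
        f = np.fft.rfftfreq(len(bvp), 1 / bvp.fs)
        peak = f[np.argmax(np.abs(np.fft.rfft(bvp.samples)) ** 2)]
        assert abs(peak - 1.0) <= 0.05


def test_chroma_series_marks_missing_frames(short_constant_beats):
    frames = simulate_face_frames(short_constant_beats, fps=30.0, seed=3)
    arr = frames.frames.copy()
    arr[5] = (0, 0, 255)
    samples = chroma_series(pk.FrameSequence(arr, fps=30.0), pk.SkinConfig(seed=7))
    assert samples[5] is None and samples[4] is not None
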