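# Methods

## Signal model and processing chain

The package assumes a quasi-periodic blood-volume pulse observed two ways:
a contact sensor sampling at 255 Hz and a camera at 30 Hz. All timing
information lives in the systolic peak times; waveform morphology is never
used downstream of peak detection. The chain is

crop(30 s, 30 s) → overlapped segmentation (300 s window, 30 s hop) →
quadratic-spline upsampling of the camera channel to 255 Hz → zero-phase
Butterworth bandpass 0.5–2.0 Hz (order 4) → peak detection → PPI →
z-score normalization → NNI → PRV indicators.

Rationale for the fixed numbers:

- **Crop 30 s / 30 s, 300 s window, 30 s hop.** An 11 min recording loses
  its unstable first and last 30 s; a 300 s window hopping by 30 s over the
  remaining 10 min yields exactly 11 overlapped segments, which is the
  protocol this pipeline mirrors. 30 s is the unique uniform hop producing
  11 segments from 600 s, since (600−300)/30 + 1 = 11. Segment counts are
  computed in samples, not seconds, so a 600.0 s signal never loses a
  segment to floating-point truncation.
- **0.5–2.0 Hz band.** 30–120 bpm covers resting adult pulse rates; the
  band also sets the peak-detection refractory period (no valid interval
  is shorter than 1/2 Hz = 0.5 s).
- **255 Hz resampling target.** Interval resolution is limited by the
  sample period; upsampling the 30 Hz camera signal to the contact rate
  (3.9 ms) before peak detection makes the two channels' interval series
  directly comparable. An interpolating (not smoothing) order-2 spline is
  used, so original samples are reproduced exactly and polynomials up to
  degree 2 are preserved.
- **z-score rule (T = 2, population SD, per segment, single pass).**
  Outlier intervals from mis-detected peaks are flagged by
  |PPI−mean|/SD ≥ 2 using the unmodified segment's statistics, and
  replaced in index order by the median of the immediately adjacent
  interval values (the mean when both neighbors exist, the single
  neighbor at a boundary). Statistics are per 300 s segment; a flag on
  `CleanConfig` is the place to change that if whole-recording statistics
  are ever wanted. The rule is symmetric in short and long intervals.

## rPPG extraction

YCbCr uses the BT.601 full-range transform — the convention of consumer
imaging pipelines. The default skin box (Y ≥ 40, 77 ≤ Cb ≤ 127,
133 ≤ Cr ≤ 173) is a widely used published range; real deployments should
expect to tune it per camera and lighting, which is why every bound is a
config field. Skin pixels are collapsed to their Cb–Cr centroid
(deterministic, and the minimal reading of "clustering" on a
two-dimensional plane with one dominant mode); the centroid is then
expanded with n = 100 isotropic Gaussian draws (SD 1.0 channel unit,
seeded) and the mean of the expanded cloud is the per-frame chroma
sample. The BVP is the standardized Cr minus standardized Cb series: the
pulse raises Cr and lowers Cb, so the difference reinforces it while
cancelling common-mode illumination drift. Respiration and slower trends
are removed by subtracting a centered moving average spanning 1/0.4 s
(content below ≈0.4 Hz), safely below the 0.5 Hz pulse-band floor.
Frames with no skin pixels are filled by linear interpolation of
neighboring chroma samples to keep the time base uniform; more than 10%
missing frames aborts the extraction. Degeneracy (a static scene) is
judged on the cluster-center series before stochastic expansion, and
constancy is tested with peak-to-peak rather than SD (the mean of n
identical floats is not bit-exact, so the SD of a constant series is
~1e-14, not 0).

Face detection and ROI tracking are out of scope: the extractor consumes
whole frames or a caller-supplied ROI box.

## PRV indicators

Mean NN and SDNN use the arithmetic mean and population SD of the
segment's intervals. Spectral indices come from the interval tachogram:
each interval is placed at its ending beat time, resampled to a uniform
4 Hz grid with the same order-2 spline, mean-removed, and passed to
Welch's method (Hann windows of 120 s, 50% overlap — about 4 averages per
300 s segment, frequency resolution ≈0.008 Hz, enough to separate the
0.04/0.15/0.4 Hz band edges). Band powers are trapezoidal integrals with
edge interpolation. VLF is 0.0033–0.04 Hz (the standard short-term HRV
convention) and total power is defined as the VLF+LF+HF integral, which
forces LFnu + HFnu = 100 exactly — a deliberate convention making the two
normalized units complementary. A constant interval series is rejected as
spectrally degenerate rather than returning noise-floor ratios.

## Synthetic data: what it emulates, what it does not

`simulate_beats` is an IPFM generator: beats fall at integer crossings of
the integrated instantaneous rate
r(t) = (bpm/60)·(1 + a_LF sin 2πf_LF t + a_HF sin 2πf_HF t), solved by
bisection to 0.1 ms using the closed-form integral. Defaults: 660 s,
75 bpm, f_LF = 0.10 Hz at depth 0.06, f_HF = 0.30 Hz at depth 0.04 —
resting-adult values giving SDNN ≈ 40 ms and LF/HF ≈ 2, i.e. mild
sympathetic dominance. Motion artifacts are Poisson-placed (default
2/min) displacements of single beats by ±0.35 of the local interval,
applied to the camera channel only — the signature of peak mis-detection
under facial motion. Rendering uses a Gaussian pulse template (FWHM
0.12 s) plus white channel noise (default SD 0.1 of unit pulse height);
morphology is deliberately schematic because only peak timing matters
downstream. Video frames color a configurable fraction of the image with
a skin tone whose Cr/Cb are modulated by ±2 channel units times the
pulse, over a static blue background; per-pixel noise defaults to zero so
the zero-modulation degenerate case stays exactly constant.

What passing tests on this generator show: the pipeline recovers beat
timing, rate, modulation frequencies and band ratios, and the
normalization step repairs artifact-corrupted intervals. What they do not
show: robustness to real PPG morphology, pulse-arrival-time physiology,
head motion, illumination change, codec artifacts, or skin-tone diversity
— none of which the generator attempts.

## Agreement scoring

MAPE uses the contact-channel indicator as the denominator (it is the
designated ground truth). Interval-level correlation pairs beats by index
after truncating to the shorter series — adequate when both channels see
the same beats, biased low when detections desynchronize, which is
accepted because it mirrors how such comparisons are reported. With
motion artifacts at the default rate the pooled per-beat NNI correlation
of a single simulated subject sits near 0.75; per-indicator correlations
computed within one subject's 11 overlapped segments are largely noise
(the segments share most of their data, so true between-segment variance
is small) and only become meaningful pooled across a multi-subject cohort
with real between-subject spread.

The bundled benchmark tables (`prvkit.benchmarks`) are per-subject MAPE
values from a published 10-subject contact-vs-camera comparison whose raw
recordings are not shareable; the package therefore reproduces the
aggregation arithmetic over those printed values (column means, deltas)
rather than the subject-level numbers themselves. The Mean-PP column of
the PPI table averages to 0.032 although the accompanying prose rounds it
to 0.033; computed values are reported.

## Numerical and scale choices

- Problem sizes in the test suite and acceptance script match the study
  protocol (660 s recordings, 11 segments) because the full pipeline runs
  in well under a second per channel; nothing is scaled down.
- All stochastic steps take explicit seeds; paired-channel runs derive
  independent child seeds from one `SeedSequence`, so results are
  bit-reproducible and channels never share noise.
- Zero-phase filtering (filtfilt) squares the Butterworth magnitude
  response and cancels phase, so detected peak times are not biased by
  filter delay; its edge transients motivate judging band attenuation away
  from segment edges in tests.
- CSVs are written with `%.17g` and read with round-trip float parsing,
  making file round-trips bit-exact.

## Known limitations

- Peak detection is a plain refractory-gated local-maximum rule; it has no
  amplitude-adaptive threshold and will chase large baseline excursions
  that survive the bandpass.
- The z-score rule assumes sparse artifacts; at artifact fractions where
  the outliers dominate the segment SD, flagged fractions drop.
- Video input is a frame directory (PNG/JPEG); container decoding is
  delegated to external tooling.
- Tachogram spectra inherit the usual HRV caveat that "frequency" is
  measured against beat-derived time; no correction for the IPFM
  spectral transfer is applied, so absolute band powers are conventions,
  not physiological constants — which is why agreement, not absolute
  power, is the evaluation target.
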