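# Methods

## The analysis chain

The pipeline reproduces the standard isolation-induced USV workflow for
mouse pups: a pup isolated from dam and littermates for 5 minutes emits
ultrasonic calls (30–120 kHz); the recording is converted to a spectrogram,
calls are segmented by an amplitude threshold with hold-time merging, four
acoustic parameters are extracted per call, sessions are summarized per
subject, and subject-level outcomes enter a 2×2 between-subjects design
(strain × social odor context).

### Spectrogram

STFT with FFT length 512, Hamming window, window length equal to the FFT
length, 75 % overlap. At 250 kHz sampling this yields a frequency bin
spacing of `250000 / 512 = 488.28 Hz` and a frame step of
`128 / 250000 = 0.512 ms` — the analytic values the pipeline's resolution
properties expose. Frames are fully contained in the signal (no boundary
padding) and time-stamped at window centers; call intervals are half-open
`[onset, offset)`.

Power is expressed in dB relative to a full-scale, bin-centered sinusoid
(0 dBFS), because detection thresholds are quoted in plain dB and digital
full scale is the only reference available without an SPL calibration.
scipy's `spectrum`/`magnitude` scaling normalizes the window, so
`dB = 20·log10(2·|X|)` puts a full-scale tone at 0. Cells with zero linear
power map to a finite floor, −120 dB by default (a numerical stand-in for
"zero energy"). The 30 kHz high-pass sets all cells below the cutoff to the
floor; it is idempotent and leaves the passband untouched.

### Detection

A frame is *active* when any passband bin exceeds the amplitude threshold
(default −40 dB). Maximal active runs become events; events separated by
silent gaps ≤ the hold time (default 10 ms) are merged, the gap counting as
part of the call (gap-bridging, not a minimum-duration rule). A separate
`min_duration` knob (default 0.5 ms) discards residual spikes. The per-bin
maximum was chosen as the frame statistic — the closest reading of an
"amplitude threshold" on a spectrogram — and the brute-force reference
oracle in the test suite uses the same definition, so the equivalence check
is about the run/merge logic, not the statistic.

Edge smearing: a 512-sample window overlapping a loud call by even a few
percent can exceed the threshold, so detected onsets/offsets are accurate
to about one window length (2.05 ms at 250 kHz), not one frame step. The
synthetic calls' 2 ms cosine ramps keep the practical error well under
that. Tests therefore bound duration errors by one window length.

### Acoustic parameters

Per call: duration (interval length); the time-averaged spectrum is
computed by averaging **linear** power across the call's frames (averaging
dB values would bias peaks toward quiet frames) and converting back to dB;
peak amplitude is that spectrum's maximum, peak frequency the frequency at
the maximum; frequency modulation (FM) is the difference between the
highest and lowest frame-wise peak frequency within the call. Frame peak
ties resolve to the lower frequency.

For near-flat spectra (long chirps spread energy almost uniformly across
the sweep band) the argmax bin is genuinely unstable under noise; this is a
property of the definition, not of the implementation. FM, by contrast, is
robust and amplitude-invariant: scaling the waveform shifts every dB cell
by a constant and leaves both the argmax bin and the peak track unchanged.

### Session summaries and exclusion rules

Call count, latency to the first call, total calling time (sum of
durations), and per-minute onset counts. A subject that never called gets
latency = session length (300 s) so the latency ANOVA can retain all
subjects — the convention implied by emission-outcome ANOVAs keeping full
residual df — while its feature means are undefined (NaN) and drop out of
feature-level statistics, which is why feature ANOVAs lose residual df and
follow-up t-tests lose 2 df when two subjects are non-callers.

### Repertoire density grids

2-D histogram over (duration, FM), default 5 ms × 5 kHz cells spanning
0–100 ms and 0–80 kHz with overflow bins, values as percentages of total
call count (pooled across subjects by default; per-subject averaging is a
caller-side option). Cluster labels are assigned by disjoint half-open
rectangles in the same plane; preset rectangle sets capture the reported
cluster geometry of each strain (four clusters for BTBR, two broader ones
for B6). Rectangles that overlap are a configuration error.

### Sequential analysis

Within each subject with more than 3 calls (and enough calls for the
longest lag), Pearson correlations between the duration sequence and
itself shifted by 1, 2, 3 calls, using the overlapping subsequences. The
group-level test is a one-sample *t* of the subject coefficients against a
chance level, df = n_subjects − 1. Chance defaults to 0; an optional
permutation mode replaces it with each subject's mean coefficient over K
within-subject shuffles.

A finite-sample caveat: the serial correlation of a randomly permuted
sequence of length n has expectation −1/(n−1), not 0, so the chance-0 test
is slightly miscalibrated for short sequences; the effect is negligible by
n ≈ a few hundred calls and the permutation mode removes it entirely. No
Fisher z-transform is applied by default (raw coefficients are what the
group test consumes); a z-transform is trivially applied by the caller if
wanted.

### Factorial statistics

Two-way between-subjects ANOVA with interaction, fit by OLS with Type-II
sums of squares — identical to the classical decomposition for balanced
cells, well-defined when excluded non-callers unbalance them. Follow-up
tests are equal-variance Student's *t* (df = nA + nB − 2, matching the
df conventions of this literature). Per-test α = 0.05 with no
multiple-testing correction by default; Holm adjustment is available. The
sex screen adds sex as a main effect to the strain × context model and
reports its p per outcome. Degenerate inputs (empty cells, zero residual
variance, constant groups) raise errors rather than returning NaN.

## The synthetic-data generator

Each synthetic call is a windowed sinusoid (2 ms raised-cosine ramps) whose
instantaneous frequency follows one of three contours — constant, linear
chirp, or sinusoidal FM (center ± depth/2, 1.5 modulation cycles per call)
— all inside the 30–120 kHz band, at a peak level given in dBFS. Sessions
are sums of non-overlapping calls (inter-call gaps forced > 12 ms, beyond
the 10 ms hold time, so true event counts are unambiguous under merging)
plus white Gaussian noise at a configurable floor (default −70 dBFS; the
background of real recordings is not characterized, so white noise is the
minimal assumption). Clipping is rejected.

Cohorts draw per-subject call counts from a negative binomial (mean,
dispersion), latencies from an exponential, onsets with a geometrically
decaying per-minute rate, durations log-normal, peak frequencies and
amplitudes normal, and contours from a mixture. The default 2×2 design
encodes the qualitative effect structure of the phenotype: BTBR cells call
~3× more than B6, start sooner, and emit longer (45 vs. 24 ms median),
louder (−18 vs. −28 dBFS), lower (65 vs. 78 kHz), more modulated (35 vs.
18 kHz span) calls; soiled bedding reduces counts ~30 % in both strains and
concentrates emission in early minutes; only B6 shows soiled-bedding
reductions in duration and FM. No published group means exist for these
quantities, so the defaults claim ordering and rough magnitude only.
`scaled_design` shortens sessions for fast experiments by scaling mean
counts and latencies proportionally.

What the generator does **not** emulate: harmonics, two-syllable/composite
calls, amplitude modulation within calls, colored or impulsive background
noise, microphone frequency response, reverberation, or litter structure
(subjects are independent). Passing tests therefore demonstrate that the
analysis chain is correct and well-calibrated for tonal calls in white
noise — not that detection is robust to every artifact of real recordings.

## Problem sizes for the calibration runs

The end-to-end operating characteristics (type-I error and power of the
context effect through the full audio chain) use replicate cohorts of
1.2 s sessions at the full 250 kHz rate with the standard STFT/detection
settings: 500 null replicates at 8 subjects per cell (mean 6 calls per
session, all cells identical) for the type-I rate, and 120 replicates at
the design's cell size of 15 (mean 10 calls clean vs. 6 soiled, a 40 %
reduction) for power. Short sessions keep the per-replicate cost near a
second while exercising every stage on real audio; the nominal level of an
F-test does not depend on session length, and power is reported at the
design's own cell size.

## Known limitations

* Peak frequency of spectrally flat calls is noise-sensitive (see above).
* Detection timing is window-limited (~2 ms), so very short gaps near the
  hold time can merge or split depending on phase alignment — exactly as
  in the thresholding tools this pipeline mirrors.
* Amplitudes are dBFS, not calibrated SPL; only within-experiment
  contrasts are meaningful.
* The ANOVA layer treats subjects as independent; litters are not modeled
  as random effects.
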