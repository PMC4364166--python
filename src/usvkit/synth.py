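"""Synthetic USV session and cohort generator with known ground truth.

Recorded cohorts are rarely shareable, so every stage of the pipeline
is exercised against synthetic 250 kHz sessions whose call inventory is known
exactly.  A session is a sum of windowed tonal calls (constant tones, linear
chirps, or sinusoidally frequency-modulated whistles, all in the 30-120 kHz
ultrasonic band) over a white Gaussian noise floor.  A cohort reproduces the
2x2 between-subjects design of the phenotyping experiment: strain (BTBR vs. B6) crossed with
social odor context (clean vs. soiled bedding), 15 pups per cell by default.

Ground truth (onsets, durations, contours, amplitudes) is retained alongside
each waveform so detection and feature extraction can be scored against it.
Calls never overlap and are separated by more than the detector's hold time,
which makes the true event count unambiguous under the gap-merging rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CallSpec",
    "GroupParams",
    "GroundTruth",
    "AudioSession",
    "synthesize_call",
    "synthesize_session",
    "synthesize_cohort",
    "paper_like_design",
    "scaled_design",
    "ground_truth_table",
    "design_to_yaml",
    "design_from_yaml",
]

CONTOURS = ("constant", "linear_chirp", "sinusoidal_fm")
FREQ_BAND_KHZ = (30.0, 120.0)
MIN_GAP_S = 0.012  # > 10 ms hold time, keeps truth events unambiguous
RAMP_S = 0.002  # raised-cosine onset/offset ramps


@dataclass(frozen=True)
class CallSpec:
    """One synthetic call: placement, duration, contour and level.

    ``f_start``/``f_end`` are the endpoint frequencies in kHz for constant
    (equal) and linear-chirp contours; for ``sinusoidal_fm`` they are the
    center frequency and the total modulation depth (kHz) respectively.
    ``amplitude_dbfs`` is the peak level relative to digital full scale
    (0 dBFS = amplitude 1.0 sinusoid), so it must be negative.
    """

    onset: float  # s from session start
    duration_ms: float
    contour: str = "constant"
    f_start_khz: float = 70.0
    f_end_khz: float = 70.0
    amplitude_dbfs: float = -20.0
    fm_cycles: float = 1.5  # sinusoidal_fm only: modulation cycles per call

    def __post_init__(self) -> None:
        if self.onset < 0:
            raise ValueError("onset must be >= 0")
        if self.duration_ms <= 0:
            raise ValueError("duration must be positive (got "
                             f"{self.duration_ms} ms)")
        if self.contour not in CONTOURS:
            raise ValueError(f"unknown contour {self.contour!r}; "
                             f"expected one of {CONTOURS}")
        lo, hi = FREQ_BAND_KHZ
        for f in self.freq_extremes():
            if not (lo < f < hi):
                raise ValueError(
                    f"contour frequency {f:.1f} kHz outside ({lo}, {hi}) kHz")
        if self.amplitude_dbfs >= 0:
            raise ValueError("amplitude must be < 0 dBFS")

    @property
    def offset(self) -> float:
        return self.onset + self.duration_ms / 1000.0

    def freq_extremes(self) -> tuple[float, float]:
        """(lowest, highest) instantaneous frequency in kHz."""
        if self.contour == "sinusoidal_fm":
            half = self.f_end_khz / 2.0
            return (self.f_start_khz - half, self.f_start_khz + half)
        return (min(self.f_start_khz, self.f_end_khz),
                max(self.f_start_khz, self.f_end_khz))

    def fm_extent_khz(self) -> float:
        """True frequency-modulation extent (highest - lowest inst. freq)."""
        lo, hi = self.freq_extremes()
        return hi - lo


@dataclass
class GroundTruth:
    """A session's true call inventory plus the seed that produced it."""

    subject_id: str
    calls: list[CallSpec]
    noise_floor_dbfs: float = -70.0
    seed: int | None = None

    def __post_init__(self) -> None:
        onsets = [c.onset for c in self.calls]
        if onsets != sorted(onsets):
            raise ValueError("calls must be sorted by onset")
        for prev, nxt in zip(self.calls, self.calls[1:]):
            if nxt.onset - prev.offset <= 0.010:
                raise ValueError(
                    "consecutive calls must be separated by a > 10 ms gap "
                    f"(got {1000 * (nxt.onset - prev.offset):.2f} ms)")

    @property
    def n_calls(self) -> int:
        return len(self.calls)


@dataclass
class AudioSession:
    """One subject's waveform plus metadata."""

    waveform: np.ndarray
    sample_rate: float
    subject_id: str = ""
    strain: str = ""
    context: str = ""
    sex: str = ""
    body_weight_g: float = np.nan
    body_temp_c: float = np.nan

    @property
    def duration_s(self) -> float:
        return self.waveform.size / self.sample_rate


def _instantaneous_phase(spec: CallSpec, t: np.ndarray) -> np.ndarray:
    """Phase (radians) of the contour at times t in [0, duration)."""
    dur = spec.duration_ms / 1000.0
    f0 = spec.f_start_khz * 1000.0
    f1 = spec.f_end_khz * 1000.0
    if spec.contour == "constant":
        return 2 * np.pi * f0 * t
    if spec.contour == "linear_chirp":
        # f(t) = f0 + (f1 - f0) t / T  ->  phi = 2pi (f0 t + (f1-f0) t^2 / 2T)
        return 2 * np.pi * (f0 * t + (f1 - f0) * t**2 / (2 * dur))
    # sinusoidal FM: f(t) = fc + (depth/2) sin(2pi fm t), fm = cycles / T
    fc = f0
    depth = f1  # already in Hz
    fm = spec.fm_cycles / dur
    return 2 * np.pi * fc * t + (depth / (2 * fm)) * (1 - np.cos(2 * np.pi * fm * t))


def synthesize_call(spec: CallSpec, sample_rate: float) -> np.ndarray:
    """Render one call as a windowed sinusoid following its contour.

    The segment has raised-cosine onset/offset ramps (~2 ms, shortened for
    very brief calls) and a peak level matching ``amplitude_dbfs`` referenced
    to a full-scale sine.
    """
    _, f_hi = spec.freq_extremes()
    if sample_rate < 2 * f_hi * 1000.0:
        raise ValueError(
            f"contour reaches {f_hi:.1f} kHz, above Nyquist for "
            f"sample rate {sample_rate:.0f} Hz")
    n = int(round(spec.duration_ms / 1000.0 * sample_rate))
    if n < 2:
        raise ValueError("call too short to render at this sample rate")
    t = np.arange(n) / sample_rate
    amp = 10.0 ** (spec.amplitude_dbfs / 20.0)
    x = amp * np.sin(_instantaneous_phase(spec, t))
    n_ramp = min(int(RAMP_S * sample_rate), n // 4)
    if n_ramp > 0:
        ramp = 0.5 * (1 - np.cos(np.pi * np.arange(n_ramp) / n_ramp))
        x[:n_ramp] *= ramp
        x[-n_ramp:] *= ramp[::-1]
    return x


def synthesize_session(truth: GroundTruth, sample_rate: float = 250_000.0,
                       session_length: float = 300.0,
                       rng: np.random.Generator | None = None) -> AudioSession:
    """Render a full session: placed calls plus Gaussian noise at the floor.

    Deterministic for a fixed ``truth.seed`` (used when ``rng`` is not
    supplied).  Raises if any call extends past the session end or if the
    mix would clip (|x| >= 1).
    """
    if rng is None:
        rng = np.random.default_rng(truth.seed)
    n = int(round(session_length * sample_rate))
    sigma = 10.0 ** (truth.noise_floor_dbfs / 20.0)
    x = rng.normal(0.0, sigma, size=n)
    for spec in truth.calls:
        if spec.offset > session_length:
            raise ValueError(
                f"call at {spec.onset:.3f} s ends after session "
                f"({spec.offset:.3f} > {session_length} s)")
        seg = synthesize_call(spec, sample_rate)
        i0 = int(round(spec.onset * sample_rate))
        x[i0:i0 + seg.size] += seg
    peak = np.abs(x).max() if n else 0.0
    if peak >= 1.0:
        raise ValueError(f"session clips (peak {peak:.3f} >= 1)")
    return AudioSession(waveform=x, sample_rate=sample_rate,
                        subject_id=truth.subject_id)


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupParams:
    """Generative parameters for one strain x context cell.

    Call counts are negative binomial (mean, dispersion ``k``; variance
    mean + mean^2/k), latency to the first call is exponential, onsets decay
    geometrically across minutes, durations are log-normal, peak frequency
    and amplitude are normal, and the contour mixture plus chirp-span
    parameters set the frequency-modulation distribution.
    """

    strain: str
    context: str
    count_mean: float = 150.0
    count_dispersion: float = 8.0
    latency_mean_s: float = 20.0
    minute_decay: float = 0.85  # call-rate multiplier per successive minute
    duration_median_ms: float = 30.0
    duration_log_sd: float = 0.45
    peak_freq_mean_khz: float = 75.0
    peak_freq_sd_khz: float = 4.0
    contour_weights: tuple[float, float, float] = (0.3, 0.4, 0.3)  # const/chirp/sinFM
    fm_span_mean_khz: float = 20.0
    fm_span_sd_khz: float = 6.0
    amp_mean_dbfs: float = -25.0
    amp_sd_db: float = 4.0

    def __post_init__(self) -> None:
        for name in ("count_mean", "count_dispersion", "latency_mean_s",
                     "minute_decay", "duration_median_ms", "duration_log_sd",
                     "peak_freq_mean_khz", "peak_freq_sd_khz",
                     "fm_span_mean_khz", "fm_span_sd_khz", "amp_sd_db"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if abs(sum(self.contour_weights) - 1.0) > 1e-9:
            raise ValueError("contour mixture weights must sum to 1")
        if self.amp_mean_dbfs >= 0:
            raise ValueError("amp_mean_dbfs must be < 0 dBFS")


def paper_like_design() -> dict[tuple[str, str], GroupParams]:
    """Default 2x2 design qualitatively matching the reported effect structure of the phenotype.

    BTBR pups call more, start sooner, and emit longer, louder,
    lower-frequency, more frequency-modulated calls than B6; soiled bedding
    lowers call counts in both strains (with emission concentrated in the
    early minutes) and shortens/flattens calls in B6 only.  No published group means exist for these
    quantities, so these values claim only the ordering, not numbers.
    """
    base = dict(count_dispersion=8.0, duration_log_sd=0.45,
                peak_freq_sd_khz=4.0, fm_span_sd_khz=6.0, amp_sd_db=4.0)
    return {
        ("BTBR", "clean"): GroupParams(
            strain="BTBR", context="clean", count_mean=450.0,
            latency_mean_s=10.0, minute_decay=0.85,
            duration_median_ms=45.0, peak_freq_mean_khz=65.0,
            contour_weights=(0.15, 0.45, 0.40), fm_span_mean_khz=35.0,
            amp_mean_dbfs=-18.0, **base),
        ("BTBR", "soiled"): GroupParams(
            strain="BTBR", context="soiled", count_mean=310.0,
            latency_mean_s=12.0, minute_decay=0.70,
            duration_median_ms=45.0, peak_freq_mean_khz=65.0,
            contour_weights=(0.15, 0.45, 0.40), fm_span_mean_khz=35.0,
            amp_mean_dbfs=-18.0, **base),
        ("B6", "clean"): GroupParams(
            strain="B6", context="clean", count_mean=150.0,
            latency_mean_s=25.0, minute_decay=0.85,
            duration_median_ms=24.0, peak_freq_mean_khz=78.0,
            contour_weights=(0.40, 0.40, 0.20), fm_span_mean_khz=18.0,
            amp_mean_dbfs=-28.0, **base),
        ("B6", "soiled"): GroupParams(
            strain="B6", context="soiled", count_mean=105.0,
            latency_mean_s=28.0, minute_decay=0.70,
            duration_median_ms=18.0, peak_freq_mean_khz=78.0,
            contour_weights=(0.45, 0.40, 0.15), fm_span_mean_khz=12.0,
            amp_mean_dbfs=-28.0, **base),
    }


def scaled_design(design: dict[tuple[str, str], GroupParams],
                  session_length: float,
                  full_length: float = 300.0) -> dict[tuple[str, str], GroupParams]:
    """Rescale a design's counts and latencies to a shorter session.

    Mean counts scale with session length and latencies shrink so that most
    subjects call; per-call feature distributions are untouched.
    """
    ratio = session_length / full_length
    out = {}
    for cell, p in design.items():
        out[cell] = GroupParams(
            **{**p.__dict__,
               "count_mean": max(p.count_mean * ratio, 1.0),
               "latency_mean_s": p.latency_mean_s * ratio})
    return out


def _sample_onsets(rng: np.random.Generator, n: int, latency: float,
                   session_length: float, minute_decay: float) -> np.ndarray:
    """Onset times with a geometrically decaying per-minute rate."""
    n_min = max(int(np.ceil(session_length / 60.0)), 1)
    starts = np.arange(n_min) * 60.0
    widths = np.minimum(60.0, session_length - starts)
    weights = minute_decay ** np.arange(n_min) * (widths / 60.0)
    weights /= weights.sum()
    minutes = rng.choice(n_min, size=n, p=weights)
    onsets = starts[minutes] + rng.uniform(0, 1, size=n) * widths[minutes]
    onsets = latency + onsets * (session_length - latency) / session_length
    return np.sort(onsets)


def _sample_truth(rng: np.random.Generator, params: GroupParams,
                  subject_id: str, session_length: float) -> GroundTruth:
    k = params.count_dispersion
    p_nb = k / (k + params.count_mean)
    n_calls = int(rng.negative_binomial(k, p_nb))
    latency = min(rng.exponential(params.latency_mean_s), session_length * 0.9)
    onsets = _sample_onsets(rng, n_calls, latency, session_length,
                            params.minute_decay)

    durations = rng.lognormal(np.log(params.duration_median_ms),
                              params.duration_log_sd, size=n_calls)
    durations = np.clip(durations, 3.0, 150.0)
    freqs = np.clip(rng.normal(params.peak_freq_mean_khz,
                               params.peak_freq_sd_khz, size=n_calls), 40.0, 110.0)
    amps = np.clip(rng.normal(params.amp_mean_dbfs, params.amp_sd_db,
                              size=n_calls), -38.0, -6.0)
    contours = rng.choice(len(CONTOURS), size=n_calls,
                          p=np.asarray(params.contour_weights))
    spans = np.abs(rng.normal(params.fm_span_mean_khz, params.fm_span_sd_khz,
                              size=n_calls))

    calls: list[CallSpec] = []
    cursor = 0.0
    for i in range(n_calls):
        onset = max(onsets[i], cursor)
        dur_s = durations[i] / 1000.0
        if onset + dur_s > session_length - 0.01:
            break  # session full; truth is the realized list
        contour = CONTOURS[contours[i]]
        f0 = float(freqs[i])
        if contour == "constant":
            f0 = float(np.clip(f0, 35.0, 115.0))
            f1 = f0
        elif contour == "linear_chirp":
            span = float(np.clip(spans[i], 1.0, 50.0))
            f1 = f0 + span if rng.uniform() < 0.5 else f0 - span
            f0 = float(np.clip(f0, 35.0, 115.0))
            f1 = float(np.clip(f1, 35.0, 115.0))
        else:  # sinusoidal_fm: f0 = center, f1 = depth
            span = float(np.clip(spans[i], 1.0, 50.0))
            f0 = float(np.clip(f0, 35.0 + span / 2 + 0.5, 115.0 - span / 2 - 0.5))
            f1 = span
        calls.append(CallSpec(onset=onset, duration_ms=float(durations[i]),
                              contour=contour, f_start_khz=f0, f_end_khz=f1,
                              amplitude_dbfs=float(amps[i])))
        cursor = onset + dur_s + MIN_GAP_S
    return GroundTruth(subject_id=subject_id, calls=calls)


def synthesize_cohort(design: dict[tuple[str, str], GroupParams],
                      n_per_cell: int = 15, seed: int = 0,
                      session_length: float = 300.0,
                      sample_rate: float = 250_000.0,
                      render_audio: bool = True,
                      ) -> list[tuple[AudioSession, GroundTruth]]:
    """Generate a full 2x2 cohort (4 x n_per_cell subjects).

    Each subject draws its call inventory from its cell's :class:`GroupParams`.
    Subject-level randomness is spawned from ``seed`` so the cohort is
    bit-reproducible.  With ``render_audio=False`` the waveform is skipped
    (sessions carry an empty array) — useful for statistics on ground truth.
    Sex is assigned alternately within each cell; body weight and temperature
    are drawn with a strain offset (BTBR pups are heavier) and no context or
    sex effect, matching the reported null results for those factors.
    """
    if n_per_cell < 2:
        raise ValueError("n_per_cell must be >= 2")
    if set(design) != {(s, c) for s in ("BTBR", "B6") for c in ("clean", "soiled")}:
        raise ValueError("design must cover the 4 strain x context cells")
    root = np.random.SeedSequence(seed)
    out: list[tuple[AudioSession, GroundTruth]] = []
    cells = sorted(design)  # deterministic order
    streams = root.spawn(len(cells) * n_per_cell)
    idx = 0
    for cell in cells:
        params = design[cell]
        for j in range(n_per_cell):
            rng = np.random.default_rng(streams[idx])
            subject_id = f"{params.strain}_{params.context}_{j:02d}"
            truth = _sample_truth(rng, params, subject_id, session_length)
            truth.seed = idx
            if render_audio:
                session = synthesize_session(truth, sample_rate,
                                             session_length, rng=rng)
            else:
                session = AudioSession(waveform=np.empty(0),
                                       sample_rate=sample_rate,
                                       subject_id=subject_id)
            session.strain = params.strain
            session.context = params.context
            session.sex = "female" if j % 2 == 0 else "male"
            weight_base = 5.2 if params.strain == "BTBR" else 4.3
            session.body_weight_g = float(rng.normal(weight_base, 0.4))
            session.body_temp_c = float(rng.normal(
                34.6 if params.strain == "BTBR" else 34.3, 0.5))
            out.append((session, truth))
            idx += 1
    return out


def design_to_yaml(design: dict[tuple[str, str], GroupParams],
                   path=None) -> str:
    """Serialize a 2x2 cohort design as YAML (keyed "strain/context")."""
    import yaml
    payload = {f"{s}/{c}": {k: (list(v) if isinstance(v, tuple) else v)
                            for k, v in p.__dict__.items()}
               for (s, c), p in design.items()}
    text = yaml.safe_dump(payload, sort_keys=True)
    if path is not None:
        from pathlib import Path
        Path(path).write_text(text)
    return text


def design_from_yaml(source) -> dict[tuple[str, str], GroupParams]:
    """Load a cohort design written by :func:`design_to_yaml`."""
    import yaml
    from pathlib import Path
    p = Path(str(source))
    text = p.read_text() if p.exists() else str(source)
    payload = yaml.safe_load(text)
    out = {}
    for key, params in payload.items():
        strain, context = key.split("/")
        params = dict(params)
        if "contour_weights" in params:
            params["contour_weights"] = tuple(params["contour_weights"])
        out[(strain, context)] = GroupParams(**params)
    return out


def ground_truth_table(truths: list[GroundTruth]) -> pd.DataFrame:
    """Flatten ground truth to a tidy table (one row per true call)."""
    rows = []
    for t in truths:
        for i, c in enumerate(t.calls):
            rows.append({
                "subject": t.subject_id, "call_index": i, "onset_s": c.onset,
                "duration_ms": c.duration_ms, "contour": c.contour,
                "f_start_khz": c.f_start_khz, "f_end_khz": c.f_end_khz,
                "amp_dbfs": c.amplitude_dbfs,
            })
    return pd.DataFrame(rows, columns=["subject", "call_index", "onset_s",
                                       "duration_ms", "contour", "f_start_khz",
                                       "f_end_khz", "amp_dbfs"])
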