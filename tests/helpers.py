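"""Shared test utilities: independent oracles and session builders.

The detection oracle here is deliberately written as a naive frame scan with
an explicit gap counter — a second, independent realization of the
threshold/hold-time contract — so the production implementation can be
checked for exact agreement.
"""

from __future__ import annotations

import numpy as np

from usvkit.detection import CallInterval, DetectionConfig
from usvkit.spectrogram import SpectrogramMatrix, StftParams, \
    apply_highpass, compute_spectrogram
from usvkit.synth import AudioSession, CallSpec, GroundTruth, \
    synthesize_session


def oracle_detect(spec: SpectrogramMatrix, cfg: DetectionConfig
                  ) -> list[CallInterval]:
    """Naive frame-scan reference for detect_calls.

    Frame-by-frame: mark a frame active when the loudest bin at/above the
    cutoff exceeds the threshold; walk the frame sequence keeping a call
    open while the running silent gap stays within the hold time.
    """
    dt = spec.time_step
    band = spec.freq_axis >= cfg.highpass_cutoff_hz
    hold_s = cfg.hold_time_ms / 1000.0
    events: list[tuple[int, int]] = []
    start = last = None
    for j in range(spec.n_frames):
        active = band.any() and spec.power[band, j].max() > cfg.amplitude_threshold_db
        if active:
            if start is None:
                start, last = j, j
            elif (j - last - 1) * dt <= hold_s + 1e-12:
                last = j
            else:
                events.append((start, last))
                start, last = j, j
    if start is not None:
        events.append((start, last))
    out = []
    for a, b in events:
        onset = max(spec.time_axis[a] - dt / 2.0, 0.0)
        offset = spec.time_axis[b] + dt / 2.0
        if (offset - onset) * 1000.0 >= cfg.min_duration_ms:
            out.append(CallInterval(onset=onset, offset=offset))
    return out


def tone_session(freq_khz: float = 70.0, duration_ms: float = 50.0,
                 amplitude_dbfs: float = -10.0, onset: float = 0.1,
                 session_length: float = 0.4, sample_rate: float = 250_000.0,
                 noise_floor: float = -70.0, seed: int = 7
                 ) -> tuple[AudioSession, GroundTruth]:
    call = CallSpec(onset=onset, duration_ms=duration_ms, contour="constant",
                    f_start_khz=freq_khz, f_end_khz=freq_khz,
                    amplitude_dbfs=amplitude_dbfs)
    truth = GroundTruth(subject_id="tone", calls=[call],
                        noise_floor_dbfs=noise_floor, seed=seed)
    return synthesize_session(truth, sample_rate, session_length), truth


def highpassed_spectrogram(session: AudioSession, cutoff: float = 30_000.0,
                           params: StftParams | None = None
                           ) -> SpectrogramMatrix:
    return apply_highpass(compute_spectrogram(session.waveform, params),
                          cutoff)


def random_truth(rng: np.random.Generator, session_length: float = 0.5,
                 max_calls: int = 10) -> GroundTruth:
    """Random small call inventory exercising gaps around the hold time."""
    calls = []
    t = rng.uniform(0.02, 0.06)
    for _ in range(rng.integers(0, max_calls + 1)):
        dur = rng.uniform(4.0, 40.0)
        if t + dur / 1000.0 > session_length - 0.02:
            break
        f = rng.uniform(40.0, 100.0)
        calls.append(CallSpec(
            onset=t, duration_ms=dur, contour="constant",
            f_start_khz=f, f_end_khz=f,
            amplitude_dbfs=float(rng.uniform(-38.0, -10.0))))
        # gaps straddle the 10 ms hold time so merging genuinely happens
        t += dur / 1000.0 + rng.uniform(0.011, 0.05)
    return GroundTruth(subject_id="rand", calls=calls, seed=int(rng.integers(2**31)))


def truth_intervals(truth: GroundTruth) -> list[CallInterval]:
    return [CallInterval(c.onset, c.offset) for c in truth.calls]
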