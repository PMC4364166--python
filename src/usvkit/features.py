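"""Per-call acoustic features and per-subject session summaries.

Four acoustic parameters are computed for each detected call, following the field's
standard definitions: call duration; peak amplitude (the highest-energy point
of the call's time-averaged spectrum, in dB); peak frequency (the frequency
at that point, kHz); and frequency modulation (the difference between the
highest and lowest frame-wise peak frequency within the call, kHz).  Session
summaries add the emission measures: total call count, latency to start
calling, total calling time, and per-minute call counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .detection import CallInterval
from .spectrogram import SpectrogramMatrix, average_spectrum, frame_peak_track

__all__ = [
    "CallRecord",
    "SessionSummary",
    "extract_features",
    "summarize_session",
    "ClusterBounds",
    "classify_cluster",
    "BTBR_CLUSTERS",
    "B6_CLUSTERS",
    "calls_table",
    "summaries_table",
]


@dataclass(frozen=True)
class CallRecord:
    interval: CallInterval
    duration_ms: float
    peak_frequency_khz: float
    peak_amplitude_db: float
    frequency_modulation_khz: float

    def __post_init__(self) -> None:
        if self.frequency_modulation_khz < 0:
            raise ValueError("frequency modulation must be >= 0")
        if self.duration_ms <= 0:
            raise ValueError("duration must be positive")


def extract_features(spec: SpectrogramMatrix, interval: CallInterval) -> CallRecord:
    """Compute the four acoustic parameters for one call interval.

    The spectrogram is expected to be high-pass filtered already, so the
    average-spectrum peak cannot fall below the cutoff band.
    """
    avg = average_spectrum(spec, interval.onset, interval.offset)
    peak_bin = int(np.argmax(avg))
    track = frame_peak_track(spec, interval.onset, interval.offset)
    return CallRecord(
        interval=interval,
        duration_ms=interval.duration_ms,
        peak_frequency_khz=spec.freq_axis[peak_bin] / 1000.0,
        peak_amplitude_db=float(avg[peak_bin]),
        frequency_modulation_khz=float(track.max() - track.min()),
    )


@dataclass
class SessionSummary:
    """Per-subject emission statistics for one session.

    A subject that never called gets ``n_calls = 0``, a latency equal to the
    session length (so the latency analysis can retain every subject), zero
    calling time, and missing (NaN) feature means — feature-level statistics
    exclude non-callers.
    """

    n_calls: int
    latency_to_first_s: float
    total_calling_time_s: float
    per_minute_counts: np.ndarray
    mean_duration_ms: float
    mean_peak_frequency_khz: float
    mean_peak_amplitude_db: float
    mean_frequency_modulation_khz: float


def summarize_session(calls: list[CallRecord], session_length: float = 300.0,
                      bin_width: float = 60.0) -> SessionSummary:
    n_bins = int(np.ceil(session_length / bin_width))
    edges = np.arange(n_bins + 1) * bin_width
    onsets = np.array([c.interval.onset for c in calls])
    if onsets.size and np.any(np.diff(onsets) < 0):
        raise ValueError("calls must be sorted by onset")
    counts, _ = np.histogram(onsets, bins=edges)
    if not calls:
        return SessionSummary(
            n_calls=0, latency_to_first_s=session_length,
            total_calling_time_s=0.0, per_minute_counts=counts,
            mean_duration_ms=np.nan, mean_peak_frequency_khz=np.nan,
            mean_peak_amplitude_db=np.nan, mean_frequency_modulation_khz=np.nan)
    return SessionSummary(
        n_calls=len(calls),
        latency_to_first_s=float(onsets[0]),
        total_calling_time_s=float(sum(c.duration_ms for c in calls)) / 1000.0,
        per_minute_counts=counts,
        mean_duration_ms=float(np.mean([c.duration_ms for c in calls])),
        mean_peak_frequency_khz=float(np.mean(
            [c.peak_frequency_khz for c in calls])),
        mean_peak_amplitude_db=float(np.mean(
            [c.peak_amplitude_db for c in calls])),
        mean_frequency_modulation_khz=float(np.mean(
            [c.frequency_modulation_khz for c in calls])),
    )


# ---------------------------------------------------------------------------
# Duration x FM cluster classification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClusterBounds:
    """A half-open rectangle [dur_lo, dur_hi) x [fm_lo, fm_hi) in
    (duration ms, FM kHz) space."""

    label: str
    dur_lo: float
    dur_hi: float
    fm_lo: float
    fm_hi: float

    def contains(self, duration_ms: float, fm_khz: float) -> bool:
        return (self.dur_lo <= duration_ms < self.dur_hi
                and self.fm_lo <= fm_khz < self.fm_hi)

    def intersects(self, other: "ClusterBounds") -> bool:
        return (self.dur_lo < other.dur_hi and other.dur_lo < self.dur_hi
                and self.fm_lo < other.fm_hi and other.fm_lo < self.fm_hi)


# Rectangles transcribed from the reported call clusters: four for BTBR
# (one short/flat cluster plus three long clusters at low, moderate and high
# FM), two broader ones for B6.
BTBR_CLUSTERS = (
    ClusterBounds("short/low-FM", 0.0, 10.0, 0.0, 10.0),
    ClusterBounds("long/low-FM", 30.0, 90.0, 0.0, 20.0),
    ClusterBounds("long/moderate-FM", 30.0, 90.0, 30.0, 40.0),
    ClusterBounds("long/high-FM", 30.0, 90.0, 40.0, 70.0),
)
B6_CLUSTERS = (
    ClusterBounds("short/low-FM", 0.0, 40.0, 0.0, 30.0),
    ClusterBounds("long/moderate-FM", 30.0, 70.0, 40.0, 50.0),
)


def classify_cluster(record: CallRecord,
                     cluster_bounds: tuple[ClusterBounds, ...]) -> str:
    """Label a call by the first rectangle containing its (duration, FM)
    point, or "unclassified".  Overlapping rectangles are a configuration
    error."""
    for i, a in enumerate(cluster_bounds):
        for b in cluster_bounds[i + 1:]:
            if a.intersects(b):
                raise ValueError(
                    f"cluster rectangles {a.label!r} and {b.label!r} overlap")
    for c in cluster_bounds:
        if c.contains(record.duration_ms, record.frequency_modulation_khz):
            return c.label
    return "unclassified"


def calls_table(records: list[CallRecord], subject: str = "",
                cluster_bounds: tuple[ClusterBounds, ...] | None = None
                ) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {"subject": subject, "onset_s": r.interval.onset,
               "duration_ms": r.duration_ms,
               "peak_freq_khz": r.peak_frequency_khz,
               "peak_amp_db": r.peak_amplitude_db,
               "fm_khz": r.frequency_modulation_khz}
        if cluster_bounds is not None:
            row["cluster"] = classify_cluster(r, cluster_bounds)
        rows.append(row)
    cols = ["subject", "onset_s", "duration_ms", "peak_freq_khz",
            "peak_amp_db", "fm_khz"]
    if cluster_bounds is not None:
        cols.append("cluster")
    return pd.DataFrame(rows, columns=cols)


def summaries_table(summaries: dict[str, SessionSummary]) -> pd.DataFrame:
    """Per-subject summary rows keyed by subject id."""
    rows = []
    for subject, s in summaries.items():
        row = {"subject": subject, "n_calls": s.n_calls,
               "latency_s": s.latency_to_first_s,
               "calling_time_s": s.total_calling_time_s,
               "mean_duration_ms": s.mean_duration_ms,
               "mean_peak_freq_khz": s.mean_peak_frequency_khz,
               "mean_peak_amp_db": s.mean_peak_amplitude_db,
               "mean_fm_khz": s.mean_frequency_modulation_khz}
        for m, c in enumerate(s.per_minute_counts):
            row[f"min{m + 1}_calls"] = int(c)
        rows.append(row)
    return pd.DataFrame(rows)
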