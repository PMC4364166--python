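"""Threshold-based call detection with a hold-time merge mechanism.

A frame of the high-pass-filtered spectrogram is *active* when any bin at or
above the high-pass cutoff exceeds the amplitude threshold (-40 dB relative
to full scale by default).  Maximal runs of active frames form raw events;
events separated by silent gaps no longer than the hold time (10 ms) are
merged into one call, the gap being bridged into the call.  This reproduces
the gap-bridging semantics of the Avisoft hold-time mechanism — it is not a
minimum-duration criterion; a separate ``min_duration`` knob (default tiny)
discards merged events that remain shorter than it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .spectrogram import SpectrogramMatrix

__all__ = ["DetectionConfig", "CallInterval", "detect_calls",
           "match_to_truth", "MatchResult", "detections_table",
           "apply_annotation_overrides"]


@dataclass(frozen=True)
class DetectionConfig:
    amplitude_threshold_db: float = -40.0
    hold_time_ms: float = 10.0
    min_duration_ms: float = 0.5
    highpass_cutoff_hz: float = 30_000.0

    def __post_init__(self) -> None:
        if self.hold_time_ms < 0:
            raise ValueError("hold_time_ms must be >= 0")
        if self.min_duration_ms < 0:
            raise ValueError("min_duration_ms must be >= 0")


@dataclass(frozen=True)
class CallInterval:
    """Half-open call interval [onset, offset) in seconds."""

    onset: float
    offset: float

    def __post_init__(self) -> None:
        if self.offset <= self.onset:
            raise ValueError("offset must exceed onset")

    @property
    def duration_ms(self) -> float:
        return (self.offset - self.onset) * 1000.0

    def overlap(self, other: "CallInterval") -> float:
        return max(0.0, min(self.offset, other.offset)
                   - max(self.onset, other.onset))


def active_frames(spec: SpectrogramMatrix, cfg: DetectionConfig) -> np.ndarray:
    """Boolean mask over frames: any bin >= cutoff exceeding the threshold."""
    band = spec.freq_axis >= cfg.highpass_cutoff_hz
    if not band.any():
        return np.zeros(spec.n_frames, dtype=bool)
    return (spec.power[band, :] > cfg.amplitude_threshold_db).any(axis=0)


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as (first, last) frame indices."""
    if not mask.any():
        return []
    idx = np.flatnonzero(mask)
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [idx.size - 1]))
    return [(int(idx[s]), int(idx[e])) for s, e in zip(starts, ends)]


def detect_calls(spec: SpectrogramMatrix,
                 cfg: DetectionConfig | None = None) -> list[CallInterval]:
    """Detect call intervals on a (high-pass-filtered) spectrogram.

    Returns intervals sorted by onset; consecutive intervals are separated by
    more than the hold time.  A frame's interval spans [center - dt/2,
    center + dt/2) so an interval of k frames has duration k x dt.
    """
    if cfg is None:
        cfg = DetectionConfig()
    mask = active_frames(spec, cfg)
    runs = _runs(mask)
    if not runs:
        return []
    dt = spec.time_step
    merged: list[list[int]] = [list(runs[0])]
    for first, last in runs[1:]:
        gap = first - merged[-1][1] - 1
        if gap * dt <= cfg.hold_time_ms / 1000.0 + 1e-12:
            merged[-1][1] = last  # bridge the gap into the call
        else:
            merged.append([first, last])
    out = []
    half = dt / 2.0
    for first, last in merged:
        onset = spec.time_axis[first] - half
        offset = spec.time_axis[last] + half
        iv = CallInterval(onset=max(onset, 0.0), offset=offset)
        if iv.duration_ms >= cfg.min_duration_ms:
            out.append(iv)
    return out


@dataclass
class MatchResult:
    """Greedy one-to-one matching of detections against ground truth."""

    true_positives: list[tuple[int, int]]  # (truth index, detection index)
    false_positives: list[int]  # unmatched detection indices
    misses: list[int]  # unmatched truth indices

    @property
    def precision(self) -> float:
        n_det = len(self.true_positives) + len(self.false_positives)
        return len(self.true_positives) / n_det if n_det else float("nan")

    @property
    def recall(self) -> float:
        n_truth = len(self.true_positives) + len(self.misses)
        return len(self.true_positives) / n_truth if n_truth else float("nan")


def match_to_truth(detections: list[CallInterval],
                   truth_intervals: list[CallInterval]) -> MatchResult:
    """Match detections to truth one-to-one by interval overlap.

    Stands in for the manual verification step of the standard workflow: each true call may
    claim at most one detection (the one overlapping it most), so a single
    detection spanning two true calls scores one hit and one miss.
    """
    taken = [False] * len(detections)
    tps: list[tuple[int, int]] = []
    misses: list[int] = []
    for ti, t in enumerate(truth_intervals):
        best, best_ov = -1, 0.0
        for di, d in enumerate(detections):
            if taken[di]:
                continue
            ov = t.overlap(d)
            if ov > best_ov:
                best, best_ov = di, ov
        if best >= 0:
            taken[best] = True
            tps.append((ti, best))
        else:
            misses.append(ti)
    fps = [di for di, used in enumerate(taken) if not used]
    return MatchResult(true_positives=tps, false_positives=fps, misses=misses)


def apply_annotation_overrides(detections: list[CallInterval],
                               add: list[CallInterval] = (),
                               remove: list[CallInterval] = ()
                               ) -> list[CallInterval]:
    """Apply a reviewer's corrections to automatic detections.

    Stands in for the manual pass in which a trained observer marks missed
    calls by hand and strikes spurious ones: every interval in ``remove``
    deletes any detection it overlaps, then the ``add`` intervals are
    inserted.  The result is sorted by onset; an added interval overlapping
    a surviving detection is a conflict and is rejected.
    """
    kept = [d for d in detections
            if not any(d.overlap(r) > 0 for r in remove)]
    for a in add:
        if any(a.overlap(d) > 0 for d in kept):
            raise ValueError(
                f"added interval [{a.onset:.3f}, {a.offset:.3f}) overlaps an "
                "existing detection; remove it first")
        kept.append(a)
    return sorted(kept, key=lambda d: d.onset)


def detections_table(detections: list[CallInterval],
                     subject: str = "") -> pd.DataFrame:
    rows = [{"subject": subject, "onset_s": d.onset, "offset_s": d.offset,
             "duration_ms": d.duration_ms} for d in detections]
    return pd.DataFrame(rows, columns=["subject", "onset_s", "offset_s",
                                       "duration_ms"])
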