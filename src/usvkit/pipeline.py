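"""End-to-end pipeline: waveforms -> calls -> summaries -> statistics.

Mirrors the standard analysis chain for a whole cohort: spectrogram with the
standard STFT settings, 30 kHz high-pass, threshold/hold-time detection,
per-call acoustic features, per-subject summaries, the 2x2 strain x context
ANOVA battery with follow-up t-tests, repertoire density grids per cell,
and the lagged-duration sequential analysis per cell.  Deterministic for
fixed inputs and configuration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .detection import CallInterval, detect_calls, detections_table
from .features import (CallRecord, SessionSummary, calls_table,
                       extract_features, summaries_table, summarize_session)
from .io import PipelineConfig, read_session
from .repertoire import SequentialResult, density_grid, sequential_analysis
from .spectrogram import apply_highpass, compute_spectrogram
from .stats import cohort_anova_report, sex_effect_screen, unpaired_t, \
    EMISSION_OUTCOMES, FEATURE_OUTCOMES
from .synth import AudioSession

__all__ = ["analyze_session", "run_pipeline", "run_pipeline_from_files",
           "PipelineResult", "cohort_table_from_summaries"]

log = logging.getLogger("usvkit")


def analyze_session(session: AudioSession, config: PipelineConfig
                    ) -> tuple[list[CallRecord], SessionSummary]:
    """Run detection + feature extraction + summary for one session."""
    spec = compute_spectrogram(session.waveform, config.stft)
    spec = apply_highpass(spec, config.detection.highpass_cutoff_hz)
    intervals = detect_calls(spec, config.detection)
    records = [extract_features(spec, iv) for iv in intervals]
    summary = summarize_session(records, config.session_length_s,
                                config.bin_width_s)
    return records, summary


def cohort_table_from_summaries(sessions: list[AudioSession],
                                summaries: list[SessionSummary]
                                ) -> pd.DataFrame:
    """Subject-level table for the factorial statistics."""
    rows = []
    for sess, s in zip(sessions, summaries):
        rows.append({"subject": sess.subject_id, "strain": sess.strain,
                     "context": sess.context, "sex": sess.sex,
                     "body_weight_g": sess.body_weight_g,
                     "body_temp_c": sess.body_temp_c,
                     "n_calls": s.n_calls, "latency_s": s.latency_to_first_s,
                     "calling_time_s": s.total_calling_time_s,
                     "mean_duration_ms": s.mean_duration_ms,
                     "mean_peak_freq_khz": s.mean_peak_frequency_khz,
                     "mean_peak_amp_db": s.mean_peak_amplitude_db,
                     "mean_fm_khz": s.mean_frequency_modulation_khz})
    df = pd.DataFrame(rows)
    if df["subject"].duplicated().any():
        raise ValueError("duplicated subject ids in cohort")
    return df


@dataclass
class PipelineResult:
    calls: pd.DataFrame  # one row per detected call
    cohort: pd.DataFrame  # one row per subject
    anova: pd.DataFrame  # tidy ANOVA rows per outcome x effect
    followup_t: pd.DataFrame  # within-strain context t-tests
    sex_screen: pd.DataFrame
    density: dict[tuple[str, str], "np.ndarray"] = field(default_factory=dict)
    sequential: dict[tuple[str, str], SequentialResult] = field(default_factory=dict)
    report: str = ""


def _followup_context_t(cohort: pd.DataFrame) -> pd.DataFrame:
    """Within each strain, clean vs. soiled unpaired t per outcome."""
    rows = []
    for outcome in (*EMISSION_OUTCOMES, *FEATURE_OUTCOMES):
        for strain in sorted(cohort["strain"].unique()):
            sub = cohort[cohort["strain"] == strain]
            a = sub.loc[sub["context"] == "clean", outcome].dropna()
            b = sub.loc[sub["context"] == "soiled", outcome].dropna()
            try:
                t, df, p = unpaired_t(a.to_numpy(), b.to_numpy())
            except ValueError:
                t, df, p = np.nan, a.size + b.size - 2, np.nan
            rows.append({"outcome": outcome, "strain": strain,
                         "t": t, "df": df, "p": p})
    return pd.DataFrame(rows)


def run_pipeline(sessions: list[AudioSession], config: PipelineConfig | None = None
                 ) -> PipelineResult:
    """Analyze a cohort of (already loaded) sessions end to end."""
    if config is None:
        config = PipelineConfig()
    log.info("pipeline config: fft=%d window=%s overlap=%.0f%% "
             "threshold=%.0f dB hold=%.1f ms highpass=%.0f Hz",
             config.stft.fft_length, config.stft.window,
             100 * config.stft.overlap_fraction,
             config.detection.amplitude_threshold_db,
             config.detection.hold_time_ms,
             config.detection.highpass_cutoff_hz)
    call_frames, summaries = [], []
    records_by_subject: dict[str, list[CallRecord]] = {}
    for sess in sessions:
        records, summary = analyze_session(sess, config)
        records_by_subject[sess.subject_id] = records
        call_frames.append(calls_table(records, subject=sess.subject_id))
        summaries.append(summary)
        log.info("subject %s: %d calls", sess.subject_id, summary.n_calls)
    nonempty = [f for f in call_frames if not f.empty]
    calls = pd.concat(nonempty, ignore_index=True) if nonempty \
        else (call_frames[0] if call_frames else pd.DataFrame())
    cohort = cohort_table_from_summaries(sessions, summaries)
    anova = cohort_anova_report(cohort)
    followup = _followup_context_t(cohort)
    sex = sex_effect_screen(cohort, EMISSION_OUTCOMES)

    density = {}
    sequential = {}
    for (strain, context), grp in cohort.groupby(["strain", "context"]):
        ids = grp["subject"].tolist()
        durs = np.concatenate([[r.duration_ms for r in records_by_subject[i]]
                               for i in ids]) if ids else np.empty(0)
        fms = np.concatenate(
            [[r.frequency_modulation_khz for r in records_by_subject[i]]
             for i in ids]) if ids else np.empty(0)
        density[(strain, context)] = density_grid(
            durs, fms, config.density_duration_bin_ms,
            config.density_fm_bin_khz)
        by_subject = {i: np.array([r.duration_ms for r in records_by_subject[i]])
                      for i in ids}
        sequential[(strain, context)] = sequential_analysis(
            by_subject, max_lag=config.sequential_max_lag,
            chance=config.sequential_chance,
            min_calls=config.sequential_min_calls,
            n_permutations=config.sequential_permutations,
            rng=np.random.default_rng(config.seed))
    report = _text_report(config, cohort, anova, followup, sequential)
    return PipelineResult(calls=calls, cohort=cohort, anova=anova,
                          followup_t=followup, sex_screen=sex,
                          density=density, sequential=sequential,
                          report=report)


def _text_report(config, cohort, anova, followup, sequential) -> str:
    lines = ["usvkit pipeline report", "=" * 40,
             f"subjects: {len(cohort)}  "
             f"(cells: {cohort.groupby(['strain', 'context']).size().to_dict()})",
             f"detection: threshold {config.detection.amplitude_threshold_db} dB, "
             f"hold {config.detection.hold_time_ms} ms, "
             f"highpass {config.detection.highpass_cutoff_hz / 1000:.0f} kHz",
             f"stft: fft {config.stft.fft_length}, {config.stft.window}, "
             f"{100 * config.stft.overlap_fraction:.0f}% overlap "
             f"({config.stft.freq_resolution:.0f} Hz x "
             f"{1000 * config.stft.time_resolution:.3f} ms)",
             "", "Two-way ANOVAs (strain x context):"]
    for outcome, grp in anova.groupby("outcome", sort=False):
        parts = [f"{r['effect']}: F(1,{r['df_den']})={r['F']:.3f} p={r['p']:.4f}"
                 for _, r in grp.iterrows()]
        lines.append(f"  {outcome}: " + "; ".join(parts))
    lines.append("")
    lines.append("Within-strain context t-tests:")
    for _, r in followup.iterrows():
        lines.append(f"  {r['outcome']} [{r['strain']}]: "
                     f"t({r['df']})={r['t']:.3f} p={r['p']:.4f}")
    lines.append("")
    lines.append("Sequential analysis (per cell):")
    for cell, res in sequential.items():
        for _, r in res.group_tests.iterrows():
            lines.append(f"  {cell}: lag {int(r['lag'])}: "
                         f"t({int(r['df'])})={r['t']:.3f} p={r['p']:.4f} "
                         f"(n={int(r['n_subjects'])})")
    return "\n".join(lines)


def run_pipeline_from_files(wav_paths: list[str | Path], metadata: pd.DataFrame,
                            config: PipelineConfig | None = None,
                            strict_rate: bool = True) -> PipelineResult:
    """Load WAV files, attach metadata by subject id, and run the pipeline.

    ``metadata`` needs columns subject, strain, context (sex and the body
    measures optional).  Files whose sampling rate mismatches the config are
    reported and skipped (continuation policy) unless none remain.
    """
    if config is None:
        config = PipelineConfig()
    if metadata.empty:
        raise ValueError("metadata table is empty")
    meta = metadata.set_index("subject")
    sessions, errors = [], []
    for p in wav_paths:
        p = Path(p)
        try:
            sess = read_session(p, expected_rate=config.stft.sample_rate)
        except ValueError as e:
            errors.append(str(e))
            log.error("skipping %s: %s", p.name, e)
            continue
        if sess.subject_id not in meta.index:
            raise ValueError(f"no metadata row for subject {sess.subject_id!r}")
        row = meta.loc[sess.subject_id]
        sess.strain = str(row["strain"])
        sess.context = str(row["context"])
        sess.sex = str(row.get("sex", ""))
        sess.body_weight_g = float(row.get("body_weight_g", np.nan))
        sess.body_temp_c = float(row.get("body_temp_c", np.nan))
        sessions.append(sess)
    if not sessions:
        raise ValueError("no readable sessions: " + "; ".join(errors))
    if errors and strict_rate:
        log.warning("%d file(s) skipped for input errors", len(errors))
    return run_pipeline(sessions, config)
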