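"""End-to-end operating characteristics of the full pipeline.

These routines answer two calibration questions about the whole chain
(synthesis -> spectrogram -> detection -> features -> 2x2 ANOVA), using
many short replicate cohorts rather than full 5-minute sessions so they run
at desk scale:

* under a null design (all four strain x context cells identical), how often
  does the context main effect on call counts reach p < 0.05?  (Should sit
  near the nominal 5%.)
* under a design where soiled bedding reduces mean call counts by 40%, how
  often is the context effect detected at the design's cell size of 15
  subjects?  (Power.)

The replicate conditions are fixed here: 1.2 s sessions at 250 kHz with the
standard STFT/detection settings, mean 6 calls per session under the null
and 10 (clean) vs. 6 (soiled) for the power design.
"""

from __future__ import annotations

import numpy as np

from .io import PipelineConfig
from .pipeline import cohort_table_from_summaries, analyze_session
from .stats import two_way_anova
from .synth import GroupParams, synthesize_cohort

__all__ = ["null_design", "context_effect_design", "context_rejection_rate",
           "REPLICATE_SESSION_S"]

REPLICATE_SESSION_S = 1.2


def _cell(strain: str, context: str, count_mean: float) -> GroupParams:
    return GroupParams(
        strain=strain, context=context, count_mean=count_mean,
        count_dispersion=8.0, latency_mean_s=0.15, minute_decay=0.9,
        duration_median_ms=25.0, duration_log_sd=0.35,
        peak_freq_mean_khz=72.0, peak_freq_sd_khz=4.0,
        contour_weights=(0.5, 0.3, 0.2), fm_span_mean_khz=15.0,
        fm_span_sd_khz=5.0, amp_mean_dbfs=-20.0, amp_sd_db=3.0)


def null_design(count_mean: float = 6.0) -> dict[tuple[str, str], GroupParams]:
    """All four cells identical: no strain, context or interaction effect."""
    return {(s, c): _cell(s, c, count_mean)
            for s in ("BTBR", "B6") for c in ("clean", "soiled")}


def context_effect_design(clean_mean: float = 10.0, reduction: float = 0.4
                          ) -> dict[tuple[str, str], GroupParams]:
    """Context main effect only: soiled bedding cuts mean counts by
    ``reduction`` (default 40%) in both strains."""
    return {(s, c): _cell(s, c, clean_mean * (1.0 - reduction)
                          if c == "soiled" else clean_mean)
            for s in ("BTBR", "B6") for c in ("clean", "soiled")}


def context_rejection_rate(design: dict[tuple[str, str], GroupParams],
                           n_replicates: int, n_per_cell: int, seed: int,
                           alpha: float = 0.05,
                           session_length: float = REPLICATE_SESSION_S
                           ) -> float:
    """Fraction of replicate cohorts whose context main effect on detected
    call counts reaches p < alpha, running the full audio pipeline."""
    cfg = PipelineConfig(session_length_s=session_length)
    root = np.random.SeedSequence(seed)
    rep_seeds = root.generate_state(n_replicates) % (2**31)
    rejections = 0
    for rep_seed in rep_seeds:
        cohort = synthesize_cohort(design, n_per_cell=n_per_cell,
                                   seed=int(rep_seed),
                                   session_length=session_length)
        sessions, summaries = [], []
        for session, _ in cohort:
            _, summary = analyze_session(session, cfg)
            sessions.append(session)
            summaries.append(summary)
        table = cohort_table_from_summaries(sessions, summaries)
        aov = two_way_anova(table, "n_calls")
        if aov.p("context") < alpha:
            rejections += 1
    return rejections / n_replicates
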