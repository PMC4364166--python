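"""Synthetic call/session/cohort generator: contracts and determinism."""

import numpy as np
import pytest

from usvkit import (CallSpec, GroundTruth, GroupParams, paper_like_design,
                    scaled_design, synthesize_call, synthesize_cohort,
                    synthesize_session)
from usvkit.synth import ground_truth_table

FS = 250_000.0


class TestSynthesizeCall:
    def test_constant_tone_dft_peak_at_requested_frequency(self):
        seg = synthesize_call(CallSpec(onset=0, duration_ms=50,
                                       f_start_khz=70, f_end_khz=70,
                                       amplitude_dbfs=-10), FS)
        assert seg.size == 12_500
        mag = np.abs(np.fft.rfft(seg))
        freqs = np.fft.rfftfreq(seg.size, 1 / FS)
        assert freqs[np.argmax(mag)] == pytest.approx(70_000.0, abs=freqs[1])

    def test_rms_level_matches_requested_dbfs(self):
        for dbfs in (-10.0, -25.0, -40.0):
            seg = synthesize_call(CallSpec(onset=0, duration_ms=50,
                                           amplitude_dbfs=dbfs), FS)
            rms_dbfs = 20 * np.log10(np.sqrt(np.mean(seg**2)) * np.sqrt(2))
            assert rms_dbfs == pytest.approx(dbfs, abs=1.0)

    def test_zero_duration_rejected(self):
        with pytest.raises(ValueError):
            CallSpec(onset=0, duration_ms=0.0)

    def test_contour_above_nyquist_rejected(self):
        spec = CallSpec(onset=0, duration_ms=10, f_start_khz=90, f_end_khz=90)
        with pytest.raises(ValueError, match="Nyquist"):
            synthesize_call(spec, 100_000.0)

    def test_out_of_band_frequency_rejected(self):
        with pytest.raises(ValueError):
            CallSpec(onset=0, duration_ms=10, f_start_khz=20, f_end_khz=20)
        with pytest.raises(ValueError):
            CallSpec(onset=0, duration_ms=10, f_start_khz=70, f_end_khz=70,
                     amplitude_dbfs=0.0)

    def test_linear_chirp_framewise_track_spans_sweep(self):
        seg = synthesize_call(CallSpec(onset=0, duration_ms=40,
                                       contour="linear_chirp",
                                       f_start_khz=60, f_end_khz=80,
                                       amplitude_dbfs=-10), FS)
        # frame-wise DFT peaks across the segment must span ~20 kHz
        n, hop = 512, 128
        peaks = []
        for start in range(0, seg.size - n, hop):
            frame = seg[start:start + n] * np.hamming(n)
            mag = np.abs(np.fft.rfft(frame))
            peaks.append(np.fft.rfftfreq(n, 1 / FS)[np.argmax(mag)])
        span = (max(peaks) - min(peaks)) / 1000.0
        assert span == pytest.approx(20.0, abs=2 * 0.48828125)

    def test_sinusoidal_fm_instantaneous_band(self):
        seg = synthesize_call(CallSpec(onset=0, duration_ms=60,
                                       contour="sinusoidal_fm",
                                       f_start_khz=70, f_end_khz=20,
                                       amplitude_dbfs=-10), FS)
        n, hop = 512, 128
        peaks = []
        for start in range(0, seg.size - n, hop):
            frame = seg[start:start + n] * np.hamming(n)
            mag = np.abs(np.fft.rfft(frame))
            peaks.append(np.fft.rfftfreq(n, 1 / FS)[np.argmax(mag)])
        peaks = np.array(peaks) / 1000.0
        assert peaks.min() == pytest.approx(60.0, abs=1.5)
        assert peaks.max() == pytest.approx(80.0, abs=1.5)


class TestSynthesizeSession:
    def test_noise_only_session_has_noise_floor_level(self):
        truth = GroundTruth(subject_id="s", calls=[], noise_floor_dbfs=-70,
                            seed=3)
        sess = synthesize_session(truth, FS, 0.5)
        assert sess.waveform.size == int(0.5 * FS)
        sigma = 10 ** (-70 / 20)
        assert np.std(sess.waveform) == pytest.approx(sigma, rel=0.05)

    def test_energy_bursts_at_specified_onsets(self):
        calls = [CallSpec(onset=t, duration_ms=30, amplitude_dbfs=-10)
                 for t in (0.10, 0.20, 0.30)]
        truth = GroundTruth(subject_id="s", calls=calls, seed=5)
        sess = synthesize_session(truth, FS, 0.5)
        env = sess.waveform**2
        frame = int(0.01 * FS)
        power = env[:env.size // frame * frame].reshape(-1, frame).mean(axis=1)
        loud = np.flatnonzero(power > power.max() / 10) * 0.01
        groups = np.split(loud, np.flatnonzero(np.diff(loud) > 0.02) + 1)
        assert len(groups) == 3
        for g, t in zip(groups, (0.10, 0.20, 0.30)):
            assert g[0] == pytest.approx(t, abs=0.011)

    def test_same_seed_gives_bit_identical_waveform(self):
        truth = GroundTruth(subject_id="s",
                            calls=[CallSpec(onset=0.1, duration_ms=20)],
                            seed=11)
        a = synthesize_session(truth, FS, 0.3).waveform
        b = synthesize_session(truth, FS, 0.3).waveform
        assert np.array_equal(a, b)

    def test_call_past_session_end_rejected(self):
        truth = GroundTruth(subject_id="s",
                            calls=[CallSpec(onset=0.29, duration_ms=20)],
                            seed=0)
        with pytest.raises(ValueError):
            synthesize_session(truth, FS, 0.3)

    def test_overlapping_or_closely_spaced_truth_rejected(self):
        a = CallSpec(onset=0.10, duration_ms=50)
        b = CallSpec(onset=0.12, duration_ms=50)  # overlaps a
        with pytest.raises(ValueError):
            GroundTruth(subject_id="s", calls=[a, b])
        c = CallSpec(onset=0.155, duration_ms=20)  # 5 ms gap < hold time
        with pytest.raises(ValueError):
            GroundTruth(subject_id="s", calls=[a, c])


class TestCohort:
    def test_paper_design_cohort_has_sixty_subjects(self):
        cohort = synthesize_cohort(paper_like_design(), n_per_cell=15,
                                   seed=0, session_length=2.0,
                                   render_audio=False)
        assert len(cohort) == 60
        cells = {(s.strain, s.context) for s, _ in cohort}
        assert len(cells) == 4

    def test_cohort_deterministic_under_seed(self):
        design = scaled_design(paper_like_design(), 2.0)
        a = synthesize_cohort(design, 2, seed=42, session_length=2.0)
        b = synthesize_cohort(design, 2, seed=42, session_length=2.0)
        for (sa, ta), (sb, tb) in zip(a, b):
            assert np.array_equal(sa.waveform, sb.waveform)
            assert ta.calls == tb.calls

    def test_preset_orders_cells_as_reported(self):
        # BTBR cells call more than B6; soiled fewer than clean within strain
        d = paper_like_design()
        assert d[("BTBR", "clean")].count_mean > d[("B6", "clean")].count_mean
        assert d[("BTBR", "soiled")].count_mean > d[("B6", "soiled")].count_mean
        for strain in ("BTBR", "B6"):
            assert d[(strain, "soiled")].count_mean \
                < 0.75 * d[(strain, "clean")].count_mean
        # BTBR: longer, louder, lower-frequency, more modulated calls
        bt, b6 = d[("BTBR", "clean")], d[("B6", "clean")]
        assert bt.duration_median_ms > b6.duration_median_ms
        assert bt.amp_mean_dbfs > b6.amp_mean_dbfs
        assert bt.peak_freq_mean_khz < b6.peak_freq_mean_khz
        assert bt.fm_span_mean_khz > b6.fm_span_mean_khz
        # B6 only: soiled bedding shortens and flattens calls
        assert d[("B6", "soiled")].duration_median_ms < b6.duration_median_ms
        assert d[("B6", "soiled")].fm_span_mean_khz < b6.fm_span_mean_khz
        assert d[("BTBR", "soiled")].duration_median_ms == bt.duration_median_ms

    def test_realized_truth_counts_follow_preset_ordering(self):
        design = scaled_design(paper_like_design(), 10.0)
        cohort = synthesize_cohort(design, n_per_cell=40, seed=1,
                                   session_length=10.0, render_audio=False)
        means = {}
        for s, t in cohort:
            means.setdefault((s.strain, s.context), []).append(t.n_calls)
        means = {k: np.mean(v) for k, v in means.items()}
        assert means[("BTBR", "clean")] > means[("B6", "clean")]
        assert means[("BTBR", "soiled")] > means[("B6", "soiled")]
        assert means[("BTBR", "soiled")] < means[("BTBR", "clean")]
        assert means[("B6", "soiled")] < means[("B6", "clean")]

    def test_truth_gaps_exceed_hold_time(self):
        design = scaled_design(paper_like_design(), 3.0)
        cohort = synthesize_cohort(design, 3, seed=2, session_length=3.0,
                                   render_audio=False)
        for _, t in cohort:
            for a, b in zip(t.calls, t.calls[1:]):
                assert b.onset - a.offset > 0.010

    def test_invalid_cohort_parameters_rejected(self):
        with pytest.raises(ValueError):
            synthesize_cohort(paper_like_design(), n_per_cell=1)
        with pytest.raises(ValueError):
            GroupParams(strain="x", context="y", count_mean=-5)
        with pytest.raises(ValueError):
            GroupParams(strain="x", context="y",
                        contour_weights=(0.5, 0.5, 0.5))

    def test_design_yaml_round_trip(self, tmp_path):
        from usvkit import design_from_yaml, design_to_yaml
        design = paper_like_design()
        path = tmp_path / "design.yaml"
        design_to_yaml(design, path)
        assert design_from_yaml(path) == design

    def test_ground_truth_table_is_tidy(self):
        design = scaled_design(paper_like_design(), 2.0)
        cohort = synthesize_cohort(design, 2, seed=3, session_length=2.0,
                                   render_audio=False)
        df = ground_truth_table([t for _, t in cohort])
        assert set(df.columns) == {"subject", "call_index", "onset_s",
                                   "duration_ms", "contour", "f_start_khz",
                                   "f_end_khz", "amp_dbfs"}
        assert df.groupby("subject")["onset_s"].apply(
            lambda s: s.is_monotonic_increasing).all()
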