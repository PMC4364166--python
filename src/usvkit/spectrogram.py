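"""dB-scaled spectrogram representation and spectral primitives.

The analysis operates on a short-time Fourier transform of the microphone
signal: 512-point FFT, Hamming window the full FFT length ("100% frame"),
75% window overlap.  At the 250 kHz sampling rate of the recordings this
yields a frequency resolution of 488 Hz and a time resolution of 0.512 ms.

Power is expressed in dB relative to a full-scale (amplitude 1.0,
bin-centered) sinusoid, so a full-scale tone reads ~0 dBFS at its bin and
detection thresholds can be quoted directly in dB.  Cells with zero linear
power are mapped to a finite floor (default -120 dB).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import spectrogram as _scipy_spectrogram
from scipy.signal.windows import get_window

__all__ = [
    "StftParams",
    "SpectrogramMatrix",
    "compute_spectrogram",
    "apply_highpass",
    "average_spectrum",
    "frame_peak_track",
]

DEFAULT_FLOOR_DB = -120.0


def _is_power_of_two(n: int) -> bool:
    return n > 0 and (n & (n - 1)) == 0


@dataclass(frozen=True)
class StftParams:
    """STFT analysis parameters.

    Defaults reproduce the Avisoft SASLab settings used for pup USV
    recordings: 512 FFT length, Hamming window, window length equal to the
    FFT length, 75% time-window overlap.
    """

    sample_rate: float = 250_000.0
    fft_length: int = 512
    window: str = "hamming"
    frame_fraction: float = 1.0
    overlap_fraction: float = 0.75

    def __post_init__(self) -> None:
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if not _is_power_of_two(self.fft_length):
            raise ValueError("fft_length must be a positive power of two")
        if not (0.0 < self.frame_fraction <= 1.0):
            raise ValueError("frame_fraction must be in (0, 1]")
        if not (0.0 <= self.overlap_fraction < 1.0):
            raise ValueError("overlap_fraction must be in [0, 1)")
        if self.window_length < 1 or self.hop < 1:
            raise ValueError("window shorter than one sample or hop of zero")

    @property
    def window_length(self) -> int:
        return int(round(self.fft_length * self.frame_fraction))

    @property
    def hop(self) -> int:
        """Frame advance in samples."""
        return int(round(self.window_length * (1.0 - self.overlap_fraction)))

    @property
    def freq_resolution(self) -> float:
        """Frequency bin spacing in Hz (sample_rate / fft_length)."""
        return self.sample_rate / self.fft_length

    @property
    def time_resolution(self) -> float:
        """Time step between frame centers in seconds (hop / sample_rate)."""
        return self.hop / self.sample_rate


@dataclass
class SpectrogramMatrix:
    """dB power grid over (frequency bin, time frame) with axis vectors."""

    power: np.ndarray  # shape (n_bins, n_frames), dB
    freq_axis: np.ndarray  # Hz per bin, strictly increasing
    time_axis: np.ndarray  # s per frame center
    params: StftParams
    floor_db: float = DEFAULT_FLOOR_DB

    @property
    def n_frames(self) -> int:
        return self.power.shape[1]

    @property
    def time_step(self) -> float:
        return self.params.time_resolution

    def frames_in(self, onset: float, offset: float) -> np.ndarray:
        """Indices of frames whose center time lies in the half-open
        interval [onset, offset)."""
        lo = int(np.searchsorted(self.time_axis, onset, side="left"))
        hi = int(np.searchsorted(self.time_axis, offset, side="left"))
        return np.arange(lo, hi)


def _db_from_magnitude(mag: np.ndarray, floor_db: float) -> np.ndarray:
    # scaling='spectrum', mode='magnitude' normalizes by the window sum, so a
    # bin-centered sinusoid of amplitude A peaks at A/2; the factor 2 puts a
    # full-scale sine at 0 dBFS.
    floor_lin = 10.0 ** (floor_db / 20.0)
    return 20.0 * np.log10(np.maximum(2.0 * mag, floor_lin))


def compute_spectrogram(waveform: np.ndarray, params: StftParams | None = None,
                        floor_db: float = DEFAULT_FLOOR_DB) -> SpectrogramMatrix:
    """Compute the dB-scaled spectrogram of a mono waveform.

    Frames are fully contained in the signal (no boundary padding) and
    time-stamped at their window centers; frequency axis spacing equals
    ``sample_rate / fft_length``.

    Raises
    ------
    ValueError
        If the waveform is shorter than one analysis window.
    """
    if params is None:
        params = StftParams()
    x = np.asarray(waveform, dtype=np.float64)
    if x.ndim != 1:
        raise ValueError("waveform must be one-dimensional (mono)")
    if x.size < params.window_length:
        raise ValueError(
            f"waveform of {x.size} samples is shorter than one analysis "
            f"window ({params.window_length} samples)"
        )
    win = get_window(params.window, params.window_length, fftbins=True)
    freqs, times, mag = _scipy_spectrogram(
        x,
        fs=params.sample_rate,
        window=win,
        nperseg=params.window_length,
        noverlap=params.window_length - params.hop,
        nfft=params.fft_length,
        detrend=False,
        scaling="spectrum",
        mode="magnitude",
    )
    power_db = _db_from_magnitude(mag, floor_db)
    return SpectrogramMatrix(power=power_db, freq_axis=freqs, time_axis=times,
                             params=params, floor_db=floor_db)


def apply_highpass(spec: SpectrogramMatrix, cutoff: float) -> SpectrogramMatrix:
    """Zero out (set to the dB floor) all cells below `cutoff` Hz.

    Mirrors the analysis step in which energy below 30 kHz — a band that
    contains no pup calls, only background noise — is reduced to zero before
    detection.  Idempotent; a cutoff of 0 returns an identical copy.
    """
    if cutoff < 0 or cutoff > spec.freq_axis[-1]:
        raise ValueError(f"cutoff {cutoff} Hz outside frequency axis range")
    power = spec.power.copy()
    power[spec.freq_axis < cutoff, :] = spec.floor_db
    return replace(spec, power=power)


def _interval_frames(spec: SpectrogramMatrix, onset: float, offset: float) -> np.ndarray:
    frames = spec.frames_in(onset, offset)
    if frames.size == 0:
        raise ValueError(
            f"interval [{onset}, {offset}) covers no spectrogram frames"
        )
    return frames


def average_spectrum(spec: SpectrogramMatrix, onset: float, offset: float) -> np.ndarray:
    """Time-averaged spectrum (dB per bin) over a call interval.

    Averaging is done on linear power — averaging dB values would bias the
    peak toward quiet frames — and converted back to dB.
    """
    frames = _interval_frames(spec, onset, offset)
    lin = 10.0 ** (spec.power[:, frames] / 10.0)
    mean_db = 10.0 * np.log10(lin.mean(axis=1))
    return np.maximum(mean_db, spec.floor_db)


def frame_peak_track(spec: SpectrogramMatrix, onset: float, offset: float) -> np.ndarray:
    """Per-frame peak frequency (kHz) over a call interval.

    For each frame the frequency of the maximum-power bin is reported; ties
    resolve to the lowest frequency (argmax returns the first maximum).
    """
    frames = _interval_frames(spec, onset, offset)
    peak_bins = np.argmax(spec.power[:, frames], axis=0)
    return spec.freq_axis[peak_bins] / 1000.0
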