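"""WAV and configuration I/O.

Recordings are mono PCM 16-bit RIFF/WAV at a nominal 250 kHz sampling rate.
Samples are normalized to [-1, 1] on read so all dB values downstream are
relative to digital full scale.  Pipeline configuration round-trips through
YAML losslessly.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy.io import wavfile

from .detection import DetectionConfig
from .spectrogram import StftParams
from .synth import AudioSession

__all__ = ["read_session", "write_session", "PipelineConfig"]

_PCM16_SCALE = 32768.0


def read_session(path: str | Path, expected_rate: float | None = 250_000.0,
                 **metadata) -> AudioSession:
    """Read a mono PCM WAV file into an :class:`AudioSession`.

    Raises on multi-channel files and on a sampling-rate mismatch with
    ``expected_rate`` (pass None to accept any rate).  Integer PCM is
    normalized to [-1, 1]; float WAVs are taken as already normalized.
    """
    path = Path(path)
    rate, data = wavfile.read(path)
    if data.ndim != 1:
        raise ValueError(f"{path.name}: expected mono audio, "
                         f"got {data.shape[1]} channels")
    if expected_rate is not None and rate != expected_rate:
        raise ValueError(f"{path.name}: sampling rate {rate} Hz does not "
                         f"match expected {expected_rate:.0f} Hz")
    if data.dtype == np.int16:
        x = data.astype(np.float64) / _PCM16_SCALE
    elif data.dtype == np.int32:
        x = data.astype(np.float64) / 2147483648.0
    elif np.issubdtype(data.dtype, np.floating):
        x = data.astype(np.float64)
    else:
        raise ValueError(f"{path.name}: unsupported PCM dtype {data.dtype}")
    return AudioSession(waveform=x, sample_rate=float(rate),
                        subject_id=metadata.pop("subject_id", path.stem),
                        **metadata)


def write_session(path: str | Path, session: AudioSession) -> None:
    """Write a session as PCM 16-bit WAV (values clipped to full scale)."""
    x = np.clip(session.waveform, -1.0, 1.0 - 1.0 / _PCM16_SCALE)
    pcm = np.round(x * _PCM16_SCALE).astype(np.int16)
    wavfile.write(Path(path), int(session.sample_rate), pcm)


@dataclass
class PipelineConfig:
    """Everything the end-to-end pipeline needs, serializable to YAML."""

    stft: StftParams = field(default_factory=StftParams)
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    session_length_s: float = 300.0
    bin_width_s: float = 60.0
    density_duration_bin_ms: float = 5.0
    density_fm_bin_khz: float = 5.0
    sequential_max_lag: int = 3
    sequential_min_calls: int = 3  # include subjects with > this many calls
    sequential_chance: float = 0.0
    sequential_permutations: int = 0
    seed: int = 0

    def to_dict(self) -> dict:
        return {"stft": asdict(self.stft),
                "detection": asdict(self.detection),
                **{k: v for k, v in asdict(self).items()
                   if k not in ("stft", "detection")}}

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        stft = StftParams(**d.pop("stft", {}))
        det = DetectionConfig(**d.pop("detection", {}))
        return cls(stft=stft, detection=det, **d)

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source: str | Path) -> "PipelineConfig":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        return cls.from_dict(yaml.safe_load(text))
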