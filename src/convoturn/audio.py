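"""Per-speaker audio containers and WAV I/O.

Recordings are assumed to be one track per speaker with no crosstalk (the
interlocutors sit in separate rooms), so a track is always mono. Samples
are held as float64 in [-1, 1]; integer PCM is rescaled on read.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.io import wavfile

__all__ = ["AudioTrack", "read_wav", "write_wav", "rms", "db"]


def rms(x: np.ndarray) -> float:
    """Root-mean-square amplitude of a sample block."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("RMS of an empty block is undefined")
    return float(np.sqrt(np.mean(np.square(x))))


def db(linear: float, floor_db: float = -120.0) -> float:
    """Convert a linear amplitude to dB FS, floored for silence."""
    if linear <= 0:
        return floor_db
    return max(20.0 * np.log10(linear), floor_db)


@dataclass
class AudioTrack:
    """One speaker's recording.

    Parameters
    ----------
    samples : ndarray
        Mono amplitude sequence, dimensionless, nominally in [-1, 1].
    sample_rate : int
        Sampling rate in Hz.
    speaker_id : str
        Speaker label, conventionally ``"A"`` or ``"B"``.
    """

    samples: np.ndarray
    sample_rate: int
    speaker_id: str = "A"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("AudioTrack requires a mono (1-D) sample array")
        if self.samples.size < 1:
            raise ValueError("AudioTrack requires at least one sample")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("AudioTrack samples must be finite")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")

    @property
    def duration(self) -> float:
        """Track duration in seconds."""
        return self.samples.size / self.sample_rate

    def slice_seconds(self, start: float, end: float) -> np.ndarray:
        """Samples of the half-open interval [start, end), rounded to the grid."""
        i0 = max(0, int(round(start * self.sample_rate)))
        i1 = min(self.samples.size, int(round(end * self.sample_rate)))
        return self.samples[i0:i1]


_INT_SCALES = {np.dtype(np.int16): 2**15, np.dtype(np.int32): 2**31, np.dtype(np.uint8): None}


def read_wav(path: str | Path, speaker_id: str = "A", channel: int | None = None) -> AudioTrack:
    """Read a WAV file into an :class:`AudioTrack`.

    PCM integer data is rescaled to [-1, 1]; float data is passed through.
    Multi-channel files require an explicit ``channel`` index.
    """
    sr, data = wavfile.read(str(path))
    if data.ndim == 2:
        if channel is None:
            raise ValueError(
                f"{path}: {data.shape[1]} channels present; per-speaker tracks must be "
                "mono (pass channel= to select one)"
            )
        data = data[:, channel]
    if data.dtype in (np.int16, np.int32):
        data = data.astype(np.float64) / _INT_SCALES[data.dtype]
    elif data.dtype == np.uint8:
        data = (data.astype(np.float64) - 128.0) / 128.0
    else:
        data = data.astype(np.float64)
    return AudioTrack(samples=data, sample_rate=int(sr), speaker_id=speaker_id)


def write_wav(path: str | Path, samples: np.ndarray, sample_rate: int) -> None:
    """Write mono float samples as 16-bit PCM WAV, clipping to full scale."""
    x = np.clip(np.asarray(samples, dtype=np.float64), -1.0, 1.0)
    pcm = np.round(x * (2**15 - 1)).astype(np.int16)
    wavfile.write(str(path), int(sample_rate), pcm)
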