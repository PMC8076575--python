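"""Audio ingestion and epoch segmentation.

Everything downstream operates on a canonical representation: mono,
float64 amplitudes in [-1, 1] at 16 kHz, cut into non-overlapping 5-second
epochs. The epoch is the unit of annotation, feature extraction and
classification throughout the package.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.io import wavfile
from scipy.signal import resample_poly

DEFAULT_SAMPLE_RATE = 16000
DEFAULT_EPOCH_SECONDS = 5.0


class AudioFormatError(ValueError):
    """Raised when a file is not a readable WAV or contains no audio."""


@dataclass(frozen=True)
class AudioSignal:
    """A mono sampled waveform.

    Parameters
    ----------
    samples : np.ndarray
        1-D float array of amplitudes in [-1, 1].
    sample_rate : int
        Sampling rate in Hz.
    """

    samples: np.ndarray
    sample_rate: int

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1:
            raise ValueError("AudioSignal requires a mono (1-D) sample array")
        if samples.size and not np.all(np.isfinite(samples)):
            raise ValueError("AudioSignal samples must be finite")
        if int(self.sample_rate) <= 0:
            raise ValueError("sample_rate must be positive")
        object.__setattr__(self, "samples", samples)
        object.__setattr__(self, "sample_rate", int(self.sample_rate))

    @property
    def duration(self) -> float:
        """Signal duration in seconds."""
        return self.samples.size / self.sample_rate


@dataclass(frozen=True)
class Epoch:
    """One non-overlapping analysis window on the 5-s grid."""

    index: int
    start_time: float
    samples: np.ndarray
    sample_rate: int

    @property
    def duration(self) -> float:
        return self.samples.size / self.sample_rate


def _pcm_to_float(data: np.ndarray) -> np.ndarray:
    """Convert the integer/float arrays scipy's WAV reader produces to [-1, 1]."""
    if data.dtype == np.uint8:  # 8-bit WAV is unsigned, midpoint 128
        return (data.astype(np.float64) - 128.0) / 128.0
    if data.dtype.kind == "i":
        return data.astype(np.float64) / float(np.iinfo(data.dtype).max + 1)
    if data.dtype.kind == "f":
        return data.astype(np.float64)
    raise AudioFormatError(f"unsupported WAV sample format: {data.dtype}")


def load_wav(path: str | Path, target_rate: int = DEFAULT_SAMPLE_RATE) -> AudioSignal:
    """Read a WAV file into the canonical representation.

    Stereo files are mixed down by channel averaging; any sample rate is
    accepted and resampled (polyphase) to ``target_rate``. Output is only
    peak-normalized when some |sample| exceeds 1 after mixdown.

    Raises
    ------
    FileNotFoundError
        If the path does not exist.
    AudioFormatError
        For non-WAV/corrupt files or zero-length audio.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"audio file not found: {path}")
    try:
        rate, data = wavfile.read(str(path))
    except FileNotFoundError:
        raise
    except Exception as exc:  # scipy raises bare ValueError on bad headers
        raise AudioFormatError(f"could not read WAV file {path}: {exc}") from exc
    if data.size == 0:
        raise AudioFormatError(f"WAV file contains no audio: {path}")

    x = _pcm_to_float(data)
    if x.ndim == 2:
        x = x.mean(axis=1)

    if rate != target_rate:
        g = math.gcd(int(target_rate), int(rate))
        x = resample_poly(x, target_rate // g, rate // g)

    peak = np.max(np.abs(x)) if x.size else 0.0
    if peak > 1.0:
        x = x / peak
    return AudioSignal(samples=x, sample_rate=target_rate)


def segment_epochs(
    signal: AudioSignal, epoch_seconds: float = DEFAULT_EPOCH_SECONDS
) -> list[Epoch]:
    """Cut a signal into non-overlapping epochs of ``epoch_seconds``.

    The trailing remainder shorter than one epoch is discarded (whole
    epochs only). A signal shorter than one epoch yields an empty list
    with a warning rather than an error.
    """
    if epoch_seconds <= 0:
        raise ValueError("epoch_seconds must be positive")
    samples_per_epoch = int(round(epoch_seconds * signal.sample_rate))
    n_epochs = signal.samples.size // samples_per_epoch
    if n_epochs == 0:
        warnings.warn(
            f"signal of {signal.duration:.2f}s is shorter than one "
            f"{epoch_seconds:g}s epoch; no epochs produced",
            stacklevel=2,
        )
        return []
    return [
        Epoch(
            index=i,
            start_time=i * epoch_seconds,
            samples=signal.samples[i * samples_per_epoch : (i + 1) * samples_per_epoch],
            sample_rate=signal.sample_rate,
        )
        for i in range(n_epochs)
    ]
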