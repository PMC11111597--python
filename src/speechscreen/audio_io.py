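"""RIFF WAV input/output and power normalization.

The screening pipeline records mono speech at 16 kHz.  Everything read
through this module is converted to that contract: integer PCM is scaled
to floating amplitudes in [-1, 1], multi-channel audio is averaged to
mono, and other sample rates are resampled (with a logged warning).

Power normalization scales an utterance to a fixed target RMS so that
downstream acoustic features do not depend on recording gain.  The target
level (default 0.1) is applied per utterance.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.io import wavfile
from scipy.signal import resample_poly

from .errors import AudioFormatError, SilentSignalError

logger = logging.getLogger(__name__)

#: Canonical pipeline sample rate in Hz.
CANONICAL_RATE = 16000

#: RMS below which a signal is treated as silent (cannot be normalized).
SILENCE_RMS = 1e-12

#: Default per-utterance RMS after power normalization.
DEFAULT_TARGET_RMS = 0.1


@dataclass(frozen=True)
class AudioSignal:
    """A mono amplitude time series with its sample rate.

    Parameters
    ----------
    samples
        1-D float array of dimensionless amplitudes, nominally in [-1, 1].
    sample_rate
        Sampling rate in Hz (positive integer).
    """

    samples: np.ndarray
    sample_rate: int

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1:
            raise AudioFormatError(
                f"AudioSignal must be mono (1-D), got shape {samples.shape}"
            )
        if not np.all(np.isfinite(samples)):
            raise AudioFormatError("AudioSignal contains non-finite samples")
        if not (isinstance(self.sample_rate, (int, np.integer)) and self.sample_rate > 0):
            raise AudioFormatError(f"sample_rate must be a positive int, got {self.sample_rate!r}")
        object.__setattr__(self, "samples", samples)
        object.__setattr__(self, "sample_rate", int(self.sample_rate))

    @property
    def duration_s(self) -> float:
        """Duration in seconds."""
        return len(self.samples) / self.sample_rate

    def __len__(self) -> int:
        return len(self.samples)


def _to_float(data: np.ndarray) -> np.ndarray:
    """Scale raw WAV sample data to float64 amplitudes in [-1, 1]."""
    if data.dtype == np.int16:
        return data.astype(np.float64) / 32768.0
    if data.dtype == np.int32:
        return data.astype(np.float64) / 2147483648.0
    if data.dtype == np.uint8:  # 8-bit WAV is unsigned, midpoint 128
        return (data.astype(np.float64) - 128.0) / 128.0
    if data.dtype in (np.float32, np.float64):
        return data.astype(np.float64)
    raise AudioFormatError(f"unsupported WAV sample format: {data.dtype}")


def read_wav(path: str | Path, target_rate: int = CANONICAL_RATE) -> AudioSignal:
    """Read a RIFF WAV file as a mono :class:`AudioSignal` at ``target_rate``.

    Multi-channel input is averaged to mono.  Input at another sample rate
    is polyphase-resampled to ``target_rate`` and a warning is logged.

    Raises
    ------
    FileNotFoundError
        If ``path`` does not exist.
    AudioFormatError
        If the file is not a valid RIFF WAV or uses an unsupported encoding.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such audio file: {path}")
    try:
        rate, data = wavfile.read(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # scipy raises ValueError on bad RIFF headers
        raise AudioFormatError(f"not a readable RIFF WAV file: {path}: {exc}") from exc

    samples = _to_float(np.asarray(data))
    if samples.ndim == 2:
        samples = samples.mean(axis=1)
    if rate != target_rate:
        logger.warning(
            "resampling %s from %d Hz to canonical %d Hz", path.name, rate, target_rate
        )
        g = math.gcd(int(rate), int(target_rate))
        samples = resample_poly(samples, target_rate // g, rate // g)
    return AudioSignal(samples=samples, sample_rate=target_rate)


def write_wav(path: str | Path, signal: AudioSignal) -> None:
    """Write an :class:`AudioSignal` as 16-bit PCM RIFF WAV."""
    clipped = np.clip(signal.samples, -1.0, 1.0)
    pcm = np.round(clipped * 32767.0).astype(np.int16)
    wavfile.write(Path(path), signal.sample_rate, pcm)


def rms(samples: np.ndarray) -> float:
    """Root-mean-square amplitude of a sample array."""
    samples = np.asarray(samples, dtype=np.float64)
    if samples.size == 0:
        return 0.0
    return float(np.sqrt(np.mean(samples**2)))


def power_normalize(
    signal: AudioSignal, target_rms: float = DEFAULT_TARGET_RMS
) -> AudioSignal:
    """Scale a signal so its RMS equals ``target_rms``.

    The output is a scalar multiple of the input, so the waveform shape
    (and every spectral feature up to a gain) is preserved.  Normalizing
    twice is a no-op up to floating-point rounding.

    Raises
    ------
    SilentSignalError
        If the signal is empty or its RMS is below :data:`SILENCE_RMS`.
    ValueError
        If ``target_rms`` is not positive.
    """
    if target_rms <= 0:
        raise ValueError(f"target_rms must be positive, got {target_rms}")
    level = rms(signal.samples)
    if level < SILENCE_RMS:
        raise SilentSignalError(
            f"signal RMS {level:.3e} below {SILENCE_RMS:.0e}; cannot power-normalize"
        )
    return AudioSignal(
        samples=signal.samples * (target_rms / level),
        sample_rate=signal.sample_rate,
    )
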