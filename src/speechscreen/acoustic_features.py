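"""MFCCs and the modulation spectrum of their temporal trajectories.

The acoustic signature used for screening is the *modulation spectrum*:
the log power spectrum of an acoustic-feature time series, here the
per-coefficient trajectories of Mel-frequency cepstral coefficients
(MFCCs).  Short-term MFCC frames capture the spectral envelope; taking a
DFT *along time* for each coefficient captures slow temporal dynamics —
syllable rate, pausing, rhythm — on the scale of a whole utterance.

The classifier consumes a fixed-length summary: the coefficient-averaged
log power at the 20 lowest non-DC modulation frequencies (~0.2–3.9 Hz at
the default 10 ms hop and 512-frame analysis length), the band where
syllabic and pause modulation of speech lives.

Numerical conventions
---------------------
* MFCC time series are mean-removed per coefficient before the temporal
  DFT, so the DC bin never dominates; DC is also excluded from the
  selected components.
* The time series is zero-padded (or truncated, with a warning) to a
  fixed analysis length so modulation bins align across utterances of
  different durations.
* Log power is floored at ``eps`` (default 1e-12) so silent coefficients
  stay finite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.fft import dct, rfft, rfftfreq

from .audio_io import AudioSignal
from .errors import TooShortError, ValidationError

logger = logging.getLogger(__name__)

#: Floor applied inside log() calls, for filterbank energies and modulation power.
LOG_FLOOR = 1e-12

#: Default fixed analysis length (frames) for the temporal DFT: ~5.12 s at 10 ms hop.
DEFAULT_MOD_FFT_FRAMES = 512

#: Number of low-order modulation components used by the classifier.
N_COMPONENTS = 20


@dataclass(frozen=True)
class MfccConfig:
    """Short-term analysis settings for MFCC extraction.

    Defaults follow common speech front-end practice: 25 ms Hamming
    frames with a 10 ms hop, 26 triangular mel filters, 13 cepstral
    coefficients including c0, and 0.97 pre-emphasis.
    """

    frame_len_s: float = 0.025
    frame_hop_s: float = 0.010
    n_mels: int = 26
    n_coeffs: int = 13
    preemphasis: float = 0.97
    fmin_hz: float = 0.0
    fmax_hz: float | None = None  # None -> Nyquist

    def __post_init__(self) -> None:
        if self.frame_hop_s <= 0:
            raise ValidationError("frame_hop_s must be positive")
        if self.frame_len_s < self.frame_hop_s:
            raise ValidationError("frame_len_s must be >= frame_hop_s")
        if self.n_coeffs < 1 or self.n_mels < self.n_coeffs:
            raise ValidationError("need 1 <= n_coeffs <= n_mels")


@dataclass(frozen=True)
class MfccMatrix:
    """MFCC trajectories: one row per frame, one column per coefficient."""

    values: np.ndarray  # (n_frames, n_coeffs)
    frame_hop_s: float
    frame_len_s: float

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        if values.ndim != 2:
            raise ValidationError(f"MFCC values must be 2-D, got shape {values.shape}")
        if not np.all(np.isfinite(values)):
            raise ValidationError("MFCC values contain non-finite entries")
        object.__setattr__(self, "values", values)

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_coeffs(self) -> int:
        return self.values.shape[1]

    @property
    def frame_rate_hz(self) -> float:
        """Sampling rate of the coefficient time series (frames per second)."""
        return 1.0 / self.frame_hop_s


@dataclass(frozen=True)
class ModulationSpectrum:
    """Per-coefficient log power spectrum of the MFCC time series."""

    log_power: np.ndarray  # (n_coeffs, n_mod_bins)
    mod_freqs: np.ndarray  # Hz, uniformly spaced from 0 (DC first)

    @property
    def n_bins(self) -> int:
        return self.log_power.shape[1]


@dataclass(frozen=True)
class ModSpecFeatures:
    """The low-order modulation components fed to the classifier."""

    components: np.ndarray  # (k,) coefficient-averaged log power
    bin_freqs: np.ndarray  # (k,) Hz of the selected modulation bins

    def __post_init__(self) -> None:
        components = np.asarray(self.components, dtype=np.float64)
        if components.ndim != 1 or not np.all(np.isfinite(components)):
            raise ValidationError("components must be a finite 1-D vector")
        object.__setattr__(self, "components", components)
        object.__setattr__(self, "bin_freqs", np.asarray(self.bin_freqs, dtype=np.float64))

    def __len__(self) -> int:
        return len(self.components)


def _hz_to_mel(f: np.ndarray | float) -> np.ndarray | float:
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=np.float64) / 700.0)


def _mel_to_hz(m: np.ndarray | float) -> np.ndarray | float:
    return 700.0 * (10.0 ** (np.asarray(m, dtype=np.float64) / 2595.0) - 1.0)


def mel_filterbank(
    n_mels: int, n_fft: int, sample_rate: int, fmin_hz: float = 0.0, fmax_hz: float | None = None
) -> np.ndarray:
    """Triangular mel filterbank, shape (n_mels, n_fft // 2 + 1).

    Filter apexes are uniformly spaced on the mel scale between
    ``fmin_hz`` and ``fmax_hz`` (default Nyquist); triangles are
    unit-peak (unnormalized area).
    """
    fmax_hz = sample_rate / 2 if fmax_hz is None else fmax_hz
    mel_points = np.linspace(_hz_to_mel(fmin_hz), _hz_to_mel(fmax_hz), n_mels + 2)
    hz_points = np.asarray(_mel_to_hz(mel_points))
    bin_freqs = np.arange(n_fft // 2 + 1) * sample_rate / n_fft
    fb = np.zeros((n_mels, len(bin_freqs)))
    for i in range(n_mels):
        lo, mid, hi = hz_points[i], hz_points[i + 1], hz_points[i + 2]
        rising = (bin_freqs - lo) / (mid - lo)
        falling = (hi - bin_freqs) / (hi - mid)
        fb[i] = np.maximum(0.0, np.minimum(rising, falling))
    return fb


def compute_mfcc(signal: AudioSignal, config: MfccConfig | None = None) -> MfccMatrix:
    """Compute MFCC trajectories for an utterance.

    Pipeline: pre-emphasis, Hamming-windowed framing, power spectrum
    (next power-of-two FFT), mel filterbank energies, log (floored at
    :data:`LOG_FLOOR`), DCT-II (orthonormal), keep the first
    ``config.n_coeffs`` coefficients including c0.

    Raises
    ------
    TooShortError
        If the signal is shorter than one frame.
    """
    config = config or MfccConfig()
    sr = signal.sample_rate
    frame_len = int(round(config.frame_len_s * sr))
    hop = int(round(config.frame_hop_s * sr))
    x = signal.samples
    if len(x) < frame_len:
        raise TooShortError(
            f"signal of {len(x)} samples shorter than one {frame_len}-sample frame"
        )
    if config.preemphasis:
        x = np.concatenate([x[:1], x[1:] - config.preemphasis * x[:-1]])

    n_frames = 1 + (len(x) - frame_len) // hop
    idx = np.arange(frame_len)[None, :] + hop * np.arange(n_frames)[:, None]
    frames = x[idx] * np.hamming(frame_len)[None, :]

    n_fft = 1 << (frame_len - 1).bit_length()
    power = np.abs(rfft(frames, n=n_fft, axis=1)) ** 2
    fb = mel_filterbank(config.n_mels, n_fft, sr, config.fmin_hz, config.fmax_hz)
    log_energies = np.log(np.maximum(power @ fb.T, LOG_FLOOR))
    cepstra = dct(log_energies, type=2, norm="ortho", axis=1)[:, : config.n_coeffs]
    return MfccMatrix(
        values=cepstra, frame_hop_s=config.frame_hop_s, frame_len_s=config.frame_len_s
    )


def compute_modulation_spectrum(
    mfcc: MfccMatrix,
    n_fft_frames: int = DEFAULT_MOD_FFT_FRAMES,
    eps: float = LOG_FLOOR,
) -> ModulationSpectrum:
    """Log power spectrum of each MFCC trajectory along time.

    Each coefficient's time series is mean-removed, zero-padded (or
    truncated, with a logged warning) to ``n_fft_frames`` frames, and
    transformed with a real DFT; the magnitude-squared spectrum is
    floored at ``eps`` before the log.  Modulation frequencies run from
    0 (DC) to half the frame rate.

    Raises
    ------
    TooShortError
        If fewer than 4 frames are available.
    """
    if mfcc.n_frames < 4:
        raise TooShortError(f"need >= 4 frames for a temporal spectrum, got {mfcc.n_frames}")
    x = mfcc.values - mfcc.values.mean(axis=0, keepdims=True)
    if x.shape[0] > n_fft_frames:
        logger.warning(
            "utterance has %d frames; truncating to analysis length %d",
            x.shape[0],
            n_fft_frames,
        )
        x = x[:n_fft_frames]
    spectrum = rfft(x, n=n_fft_frames, axis=0)  # (n_bins, n_coeffs)
    log_power = np.log(np.maximum(np.abs(spectrum) ** 2, eps)).T
    mod_freqs = rfftfreq(n_fft_frames, d=mfcc.frame_hop_s)
    return ModulationSpectrum(log_power=log_power, mod_freqs=mod_freqs)


def extract_low_order_components(
    modspec: ModulationSpectrum, k: int = N_COMPONENTS
) -> ModSpecFeatures:
    """Coefficient-averaged log power at the ``k`` lowest non-DC bins.

    Averaging across cepstral coefficients yields one log-power value per
    modulation frequency; the ``k`` lowest-frequency bins above DC, in
    increasing frequency order, form the utterance's acoustic feature
    vector.

    Raises
    ------
    ValidationError
        If ``k <= 0`` or ``k >= n_mod_bins``.
    """
    if k <= 0 or k >= modspec.n_bins:
        raise ValidationError(
            f"k must satisfy 0 < k < n_mod_bins ({modspec.n_bins}), got {k}"
        )
    averaged = modspec.log_power.mean(axis=0)
    return ModSpecFeatures(
        components=averaged[1 : k + 1], bin_freqs=modspec.mod_freqs[1 : k + 1]
    )


def acoustic_feature_names(k: int = N_COMPONENTS) -> list[str]:
    """Column names for exported component vectors: ms_01 .. ms_k."""
    return [f"ms_{i:02d}" for i in range(1, k + 1)]


def extract_features(
    signal: AudioSignal,
    config: MfccConfig | None = None,
    n_fft_frames: int = DEFAULT_MOD_FFT_FRAMES,
    k: int = N_COMPONENTS,
) -> ModSpecFeatures:
    """Convenience pipeline: signal -> MFCC -> modulation spectrum -> components."""
    mfcc = compute_mfcc(signal, config)
    modspec = compute_modulation_spectrum(mfcc, n_fft_frames=n_fft_frames)
    return extract_low_order_components(modspec, k=k)
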