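"""Exception hierarchy.

Every error raised by the package derives from :class:`SpeechScreenError`,
so callers (and the CLI exit-code mapping) can catch one base class.
"""


class SpeechScreenError(Exception):
    """Base class for all package errors."""


class AudioFormatError(SpeechScreenError):
    """File is not a readable RIFF WAV, or uses an unsupported encoding."""


class SilentSignalError(SpeechScreenError):
    """Signal has no energy; power normalization is undefined."""


class TooShortError(SpeechScreenError):
    """Input too short for the requested analysis (frames / modulation DFT)."""


class ConfigurationError(SpeechScreenError):
    """Invalid or missing configuration (rules, backends, generator params)."""


class TranscriptionError(SpeechScreenError):
    """A transcription backend failed to produce text."""


class AgeExclusionError(SpeechScreenError):
    """Age outside the study range [20, 100)."""


class DimensionError(SpeechScreenError):
    """Feature vector shape or signature mismatch."""


class ValidationError(SpeechScreenError):
    """Malformed data: bad labels, negative counts, schema violations."""


class DegenerateTrainingError(SpeechScreenError):
    """Training set cannot support a classifier (e.g. a single class)."""


class ModelCompatibilityError(SpeechScreenError):
    """Persisted model cannot be loaded (corrupt file or version mismatch)."""


class EnumerationBudgetError(SpeechScreenError):
    """Exact-test enumeration would exceed the configured table budget."""
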