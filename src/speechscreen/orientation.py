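"""Time-orientation task: transcription backends and 0–4 scoring.

The screening question asks for today's date in the Western calendar:
year, month, day of the month, and day of the week.  Each of the four
elements found correct in the transcript earns one point, for a score
between 0 and 4 — the time-orientation item of standard dementia
screening scales, scored automatically.

Matching is deterministic and set-based: the transcript is normalized
(Unicode NFKC, case-folded) and scanned for *candidates* of each element
under a locale rule set.  An element is

* ``CORRECT``  if its candidate set is exactly the reference value,
* ``INCORRECT`` if candidates exist but include a wrong value,
* ``ABSENT``  if no candidate is found.

Only ``CORRECT`` scores a point; the rubric is additive and order-free.
Exact match is required (no off-by-one-day tolerance).  The reference
date is an explicit argument, never the wall clock, so results are
reproducible.

Rule sets are JSON data files (``locales/``).  The English rules are
token-based with numeral-word support ("twenty fifth" = 25); the
Japanese rules are pattern-based, keying on the 年/月/日/曜 suffixes.

Speech-to-text is pluggable: a :class:`Transcriber` backend maps audio
to text.  The package ships a mock backend (fixed id → text map) and a
sidecar-file backend (reads ``<audio>.txt``); a cloud recognizer can be
registered by the caller.
"""

from __future__ import annotations

import datetime as _dt
import json
import re
import unicodedata
from abc import ABC, abstractmethod
from dataclasses import dataclass
from enum import Enum
from importlib import resources
from pathlib import Path

from .audio_io import AudioSignal
from .errors import ConfigurationError, TranscriptionError, ValidationError

ELEMENTS = ("year", "month", "day", "weekday")

MAX_SCORE = 4


class ElementStatus(Enum):
    CORRECT = "correct"
    INCORRECT = "incorrect"
    ABSENT = "absent"


@dataclass(frozen=True)
class TaskScore:
    """Integer task score in 0..4 (one point per correct element)."""

    value: int

    def __post_init__(self) -> None:
        if not (0 <= self.value <= MAX_SCORE):
            raise ValidationError(f"task score must be in 0..{MAX_SCORE}, got {self.value}")


@dataclass(frozen=True)
class OrientationResponse:
    """Per-element scoring detail for one transcript."""

    transcript: str
    reference_date: _dt.date
    element_results: dict[str, ElementStatus]


class LocaleRules:
    """A locale's matching rules, loaded from a JSON rule file."""

    def __init__(self, data: dict):
        style = data.get("style")
        if style not in ("token", "pattern"):
            raise ConfigurationError(f"rule set style must be 'token' or 'pattern', got {style!r}")
        self.style = style
        self.data = data
        if style == "token":
            if not data.get("weekdays") or not data.get("months"):
                raise ConfigurationError("token rule set needs weekday and month synonym lists")
            self.weekday_syn = {
                syn: i for i, syns in enumerate(data["weekdays"]) for syn in syns
            }
            self.month_syn = {
                syn: i + 1 for i, syns in enumerate(data["months"]) for syn in syns
            }
            self.cardinal = {k: int(v) for k, v in data.get("cardinal", {}).items()}
            self.ordinal = {k: int(v) for k, v in data.get("ordinal", {}).items()}
        else:
            for key in ("year_pattern", "month_pattern", "day_pattern", "weekday_pattern"):
                if key not in data:
                    raise ConfigurationError(f"pattern rule set missing {key}")
            self.patterns = {
                "year": re.compile(data["year_pattern"]),
                "month": re.compile(data["month_pattern"]),
                "day": re.compile(data["day_pattern"]),
                "weekday": re.compile(data["weekday_pattern"]),
            }
            self.weekday_chars = {k: int(v) for k, v in data["weekday_chars"].items()}


def load_rules(locale: str | Path | LocaleRules = "en") -> LocaleRules:
    """Load a locale rule set by name ('en', 'ja') or from a JSON file path."""
    if isinstance(locale, LocaleRules):
        return locale
    path = Path(locale)
    if path.suffix == ".json" and path.exists():
        return LocaleRules(json.loads(path.read_text(encoding="utf-8")))
    try:
        text = (resources.files("speechscreen.locales") / f"{locale}.json").read_text(
            encoding="utf-8"
        )
    except FileNotFoundError:
        raise ConfigurationError(f"unknown locale rule set: {locale!r}") from None
    return LocaleRules(json.loads(text))


def _normalize(text: str) -> str:
    return unicodedata.normalize("NFKC", text).casefold()


_ORDINAL_DIGIT = re.compile(r"^(\d{1,2})(st|nd|rd|th)$")


def _token_candidates(transcript: str, rules: LocaleRules) -> dict[str, set[int]]:
    """Candidate values per element from a token-based (English-style) rule set."""
    tokens = re.split(r"[^0-9a-z]+", _normalize(transcript.replace("-", " ")))
    tokens = [t for t in tokens if t]

    numbers: list[int] = []  # cardinal values, incl. digit strings
    day_like: set[int] = set()  # ordinals and small numbers usable as day-of-month
    weekdays: set[int] = set()
    months: set[int] = set()

    i = 0
    while i < len(tokens):
        tok = tokens[i]
        if tok in rules.weekday_syn:
            weekdays.add(rules.weekday_syn[tok])
        elif tok in rules.month_syn:
            months.add(rules.month_syn[tok])
        elif tok.isdigit():
            numbers.append(int(tok))
        elif m := _ORDINAL_DIGIT.match(tok):
            day_like.add(int(m.group(1)))
        elif tok in rules.cardinal:
            value = rules.cardinal[tok]
            # compound "twenty five" / "twenty fifth"
            if value % 10 == 0 and 20 <= value <= 90 and i + 1 < len(tokens):
                nxt = tokens[i + 1]
                if nxt in rules.cardinal and 1 <= rules.cardinal[nxt] <= 9:
                    numbers.append(value + rules.cardinal[nxt])
                    i += 2
                    continue
                if nxt in rules.ordinal and 1 <= rules.ordinal[nxt] <= 9:
                    day_like.add(value + rules.ordinal[nxt])
                    i += 2
                    continue
            numbers.append(value)
        elif tok in rules.ordinal:
            day_like.add(rules.ordinal[tok])
        i += 1

    years = {n for n in numbers if 1000 <= n <= 9999}
    day_like |= {n for n in numbers if 1 <= n <= 31}
    return {"year": years, "month": months, "day": day_like, "weekday": weekdays}


def _pattern_candidates(transcript: str, rules: LocaleRules) -> dict[str, set[int]]:
    """Candidate values per element from a pattern-based (Japanese-style) rule set."""
    text = _normalize(transcript)
    out: dict[str, set[int]] = {}
    for element in ("year", "month", "day"):
        out[element] = {int(m) for m in rules.patterns[element].findall(text)}
    out["weekday"] = {
        rules.weekday_chars[c]
        for c in rules.patterns["weekday"].findall(text)
        if c in rules.weekday_chars
    }
    return out


def score_response(
    transcript: str,
    reference_date: _dt.date | str,
    rules: str | Path | LocaleRules = "en",
) -> tuple[TaskScore, OrientationResponse]:
    """Score a transcript against the reference date, one point per element.

    Parameters
    ----------
    transcript
        The (possibly empty) recognized text of the spoken response.
    reference_date
        The true current date, as a :class:`datetime.date` or ISO string.
    rules
        Locale rule set: a name ('en', 'ja'), a JSON file path, or a
        loaded :class:`LocaleRules`.

    Returns
    -------
    (TaskScore, OrientationResponse)
        The 0–4 score and the per-element correct/incorrect/absent map.
    """
    if isinstance(reference_date, str):
        try:
            reference_date = _dt.date.fromisoformat(reference_date)
        except ValueError as exc:
            raise ValidationError(f"invalid reference date: {exc}") from exc
    if not isinstance(reference_date, _dt.date):
        raise ValidationError(f"reference_date must be a date, got {type(reference_date)}")
    rule_set = load_rules(rules)

    extractor = _token_candidates if rule_set.style == "token" else _pattern_candidates
    candidates = extractor(transcript, rule_set)
    truth = {
        "year": reference_date.year,
        "month": reference_date.month,
        "day": reference_date.day,
        "weekday": reference_date.weekday(),  # Monday = 0
    }
    results: dict[str, ElementStatus] = {}
    for element in ELEMENTS:
        found = candidates[element]
        if not found:
            results[element] = ElementStatus.ABSENT
        elif found == {truth[element]}:
            results[element] = ElementStatus.CORRECT
        else:
            results[element] = ElementStatus.INCORRECT
    score = sum(1 for s in results.values() if s is ElementStatus.CORRECT)
    return TaskScore(score), OrientationResponse(transcript, reference_date, results)


def format_response(date: _dt.date, rules: str | LocaleRules = "en") -> str:
    """Render a fully correct spoken-style answer for ``date`` (used by the
    synthetic cohort generator; English token style only)."""
    weekday_names = ("monday", "tuesday", "wednesday", "thursday", "friday", "saturday", "sunday")
    month_names = (
        "january", "february", "march", "april", "may", "june",
        "july", "august", "september", "october", "november", "december",
    )
    return (
        f"today is {weekday_names[date.weekday()]} "
        f"{month_names[date.month - 1]} {date.day} {date.year}"
    )


# ---------------------------------------------------------------------------
# Transcription backends
# ---------------------------------------------------------------------------


class Transcriber(ABC):
    """Interface mapping an audio reference to recognized text."""

    @abstractmethod
    def transcribe(self, audio: AudioSignal | Path | None, record_id: str | None = None) -> str:
        """Return the transcript for the given audio (or record id)."""


class MockTranscriber(Transcriber):
    """Fixed id → transcript map; used in tests and simulations."""

    def __init__(self, mapping: dict[str, str]):
        self.mapping = dict(mapping)

    def transcribe(self, audio=None, record_id: str | None = None) -> str:
        if record_id not in self.mapping:
            raise TranscriptionError(f"no mock transcript registered for id {record_id!r}")
        return self.mapping[record_id]


class SidecarFileTranscriber(Transcriber):
    """Reads the transcript from a UTF-8 ``.txt`` file next to the audio."""

    def transcribe(self, audio: Path | str | None = None, record_id: str | None = None) -> str:
        if audio is None:
            raise TranscriptionError("sidecar backend needs the audio file path")
        sidecar = Path(audio).with_suffix(".txt")
        if not sidecar.exists():
            raise TranscriptionError(f"no sidecar transcript: {sidecar}")
        return sidecar.read_text(encoding="utf-8").strip()


_BACKENDS: dict[str, type[Transcriber]] = {
    "mock": MockTranscriber,
    "sidecar": SidecarFileTranscriber,
}


def register_backend(name: str, cls: type[Transcriber]) -> None:
    """Register a transcription backend class under ``name``."""
    _BACKENDS[name] = cls


def get_backend(name: str, **kwargs) -> Transcriber:
    """Instantiate a registered backend by name."""
    if name not in _BACKENDS:
        raise ConfigurationError(
            f"no transcription backend named {name!r}; registered: {sorted(_BACKENDS)}"
        )
    return _BACKENDS[name](**kwargs)


def transcribe(
    audio: AudioSignal | Path | None,
    backend: Transcriber | str | None,
    record_id: str | None = None,
    **backend_kwargs,
) -> str:
    """Transcribe audio through a backend instance or registered name."""
    if backend is None:
        raise ConfigurationError("no transcription backend configured")
    if isinstance(backend, str):
        backend = get_backend(backend, **backend_kwargs)
    try:
        return backend.transcribe(audio, record_id=record_id)
    except TranscriptionError:
        raise
    except Exception as exc:
        raise TranscriptionError(f"transcription backend failed: {exc}") from exc
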