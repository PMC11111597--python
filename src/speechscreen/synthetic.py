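"""Synthetic cohorts for developing and stress-testing the screening pipeline.

No audio or per-subject data from the clinical study are available, so
this module generates cohorts with the statistical structure the
classifier assumes:

* **Demographics** — participants per facility × diagnosis stratum with
  ages drawn from a truncated normal on [20, 100), defaulting to the
  study's published stratum sizes and age moments (489 dementia / 1097
  cognitively normal across facilities A, B, C).
* **Orientation responses** — transcripts built from the reference date
  with each of the four elements (year, month, day, weekday)
  independently flipped to a wrong value with a class-dependent error
  probability, so transcript and score stay mutually consistent.
* **Audio** — syllable-like amplitude-modulated bursts of band-limited
  noise at a class-dependent syllable rate and pause fraction, so the
  temporal modulation spectrum differs between classes in a controlled,
  recoverable way (slower, pause-heavier speech for the dementia class).

The generator also provides an exact predictions fixture reproducing the
published per-facility confusion counts, used by the evaluation layer's
tests and the reproduction script.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.signal import butter, sosfilt
from scipy.stats import truncnorm

from .audio_io import AudioSignal, CANONICAL_RATE, power_normalize
from .classifier import AGE_MAX, AGE_MIN, NEGATIVE_LABEL, POSITIVE_LABEL
from .errors import ConfigurationError, ValidationError
from .orientation import score_response
from .evaluation import percent_half_up

_WEEKDAY_NAMES = ("monday", "tuesday", "wednesday", "thursday", "friday", "saturday", "sunday")
_MONTH_NAMES = (
    "january", "february", "march", "april", "may", "june",
    "july", "august", "september", "october", "november", "december",
)

#: Default reference date for synthetic responses (end of the collection window).
DEFAULT_REFERENCE_DATE = _dt.date(2022, 11, 30)


@dataclass(frozen=True)
class ClassParams:
    """Per-diagnosis effect sizes driving the generator.

    element_error_prob
        Probability that each orientation element is answered wrongly.
    syllable_rate_hz
        Syllabic burst rate of the synthesized speech (Hz).
    pause_fraction
        Fraction of each syllable period that is silent.
    """

    element_error_prob: float
    syllable_rate_hz: float
    pause_fraction: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.element_error_prob <= 1.0):
            raise ConfigurationError("element_error_prob must be in [0, 1]")
        if not (0.0 <= self.pause_fraction < 1.0):
            raise ConfigurationError("pause_fraction must be in [0, 1)")


DEMENTIA_PARAMS = ClassParams(element_error_prob=0.45, syllable_rate_hz=3.5, pause_fraction=0.35)
NORMAL_PARAMS = ClassParams(element_error_prob=0.05, syllable_rate_hz=5.5, pause_fraction=0.15)


@dataclass(frozen=True)
class StratumConfig:
    """One facility × diagnosis cell: size and age distribution."""

    facility: str
    diagnosis: str
    n: int
    age_mean: float
    age_sd: float

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ConfigurationError("stratum n must be >= 0")
        if self.age_sd <= 0:
            raise ConfigurationError("age_sd must be positive")
        if self.diagnosis not in (POSITIVE_LABEL, NEGATIVE_LABEL):
            raise ConfigurationError(f"unknown diagnosis {self.diagnosis!r}")


#: Published stratum sizes and age moments (facility × diagnosis).
STUDY_STRATA: tuple[StratumConfig, ...] = (
    StratumConfig("A", POSITIVE_LABEL, 284, 78.6, 9.7),
    StratumConfig("A", NEGATIVE_LABEL, 498, 70.6, 13.8),
    StratumConfig("B", POSITIVE_LABEL, 187, 82.0, 6.5),
    StratumConfig("B", NEGATIVE_LABEL, 557, 78.4, 9.2),
    StratumConfig("C", POSITIVE_LABEL, 18, 78.4, 8.8),
    StratumConfig("C", NEGATIVE_LABEL, 42, 54.3, 17.7),
)


@dataclass(frozen=True)
class CohortConfig:
    """Full generator configuration; deterministic for a fixed seed."""

    strata: tuple[StratumConfig, ...] = STUDY_STRATA
    class_params: tuple[tuple[str, ClassParams], ...] = (
        (POSITIVE_LABEL, DEMENTIA_PARAMS),
        (NEGATIVE_LABEL, NORMAL_PARAMS),
    )
    seed: int = 1
    audio_duration_s: float = 4.0
    reference_date: _dt.date = DEFAULT_REFERENCE_DATE

    def params_for(self, diagnosis: str) -> ClassParams:
        for label, params in self.class_params:
            if label == diagnosis:
                return params
        raise ConfigurationError(f"no class params for {diagnosis!r}")

    @classmethod
    def study_default(cls, seed: int = 1) -> "CohortConfig":
        """The published cohort structure (489 dementia / 1097 normal)."""
        return cls(seed=seed)

    @classmethod
    def balanced(cls, n_per_class: int = 200, seed: int = 42) -> "CohortConfig":
        """A balanced single-facility cohort with pooled age moments."""
        return cls(
            strata=(
                StratumConfig("A", POSITIVE_LABEL, n_per_class, 79.9, 8.7),
                StratumConfig("A", NEGATIVE_LABEL, n_per_class, 73.9, 13.1),
            ),
            seed=seed,
        )

    @classmethod
    def null(cls, n_per_class: int = 200, seed: int = 0) -> "CohortConfig":
        """Zero class separation: identical ages, errors and audio for
        both labels.  Any classifier accuracy above chance on held-out
        data from this config indicates leakage."""
        shared = ClassParams(element_error_prob=0.25, syllable_rate_hz=4.5, pause_fraction=0.25)
        return cls(
            strata=(
                StratumConfig("A", POSITIVE_LABEL, n_per_class, 75.0, 10.0),
                StratumConfig("A", NEGATIVE_LABEL, n_per_class, 75.0, 10.0),
            ),
            class_params=((POSITIVE_LABEL, shared), (NEGATIVE_LABEL, shared)),
            seed=seed,
        )


@dataclass
class ParticipantRecord:
    """One synthetic participant and the pipeline state derived so far."""

    id: str
    facility: str
    age: float
    diagnosis: str
    transcript: str | None = None
    score: int | None = None
    audio: AudioSignal | None = None
    audio_seed: int | None = None
    predicted: str | None = None


def _truncnorm_ages(rng: np.random.Generator, n: int, mean: float, sd: float) -> np.ndarray:
    a, b = (AGE_MIN - mean) / sd, (AGE_MAX - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)


def _wrong_value(rng: np.random.Generator, correct: int, lo: int, hi: int) -> int:
    """A uniform draw from [lo, hi] excluding the correct value."""
    v = int(rng.integers(lo, hi))  # hi exclusive -> one fewer option
    return v if v < correct else v + 1


def _make_transcript(rng: np.random.Generator, date: _dt.date, error_prob: float) -> str:
    year, month, day, weekday = date.year, date.month, date.day, date.weekday()
    if rng.random() < error_prob:
        year = _wrong_value(rng, date.year, date.year - 5, date.year + 5)
    if rng.random() < error_prob:
        month = _wrong_value(rng, date.month, 1, 12)
    if rng.random() < error_prob:
        day = _wrong_value(rng, date.day, 1, 28)
    if rng.random() < error_prob:
        weekday = _wrong_value(rng, date.weekday(), 0, 6)
    return f"today is {_WEEKDAY_NAMES[weekday]} {_MONTH_NAMES[month - 1]} {day} {year}"


def synthesize_response_audio(
    params: ClassParams,
    duration_s: float = 4.0,
    seed: int = 0,
    sample_rate: int = CANONICAL_RATE,
) -> AudioSignal:
    """Synthesize a syllable-like spoken-response stand-in.

    Band-limited noise (300–3000 Hz) is gated by a train of raised-cosine
    bursts at ``params.syllable_rate_hz`` with ``params.pause_fraction``
    of each period silent, then power-normalized.  The envelope's
    temporal modulation therefore peaks near the syllable rate, which is
    what the modulation-spectrum features pick up.

    Raises :class:`ConfigurationError` for duration <= 0.2 s or a
    syllable rate outside (0, 20] Hz.
    """
    if duration_s <= 0.2:
        raise ConfigurationError(f"duration_s must exceed 0.2 s, got {duration_s}")
    if not (0.0 < params.syllable_rate_hz <= 20.0):
        raise ConfigurationError(
            f"syllable rate must be in (0, 20] Hz, got {params.syllable_rate_hz}"
        )
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * sample_rate))

    sos = butter(4, [300.0, 3000.0], btype="bandpass", fs=sample_rate, output="sos")
    carrier = sosfilt(sos, rng.standard_normal(n))

    period = int(round(sample_rate / params.syllable_rate_hz))
    burst_len = max(2, int(round(period * (1.0 - params.pause_fraction))))
    envelope = np.zeros(n)
    for start in range(0, n, period):
        stop = min(start + burst_len, n)
        window = np.hanning(burst_len)[: stop - start]
        envelope[start:stop] = window * rng.uniform(0.7, 1.3)

    return power_normalize(AudioSignal(samples=carrier * envelope, sample_rate=sample_rate))


def generate_cohort(
    config: CohortConfig | None = None, with_audio: bool = False
) -> list[ParticipantRecord]:
    """Generate a cohort of participants per the configuration.

    Records come out stratum by stratum in configuration order, with
    unique ids, transcripts scored through the orientation module, and
    (optionally) synthesized audio.  The same config and seed always
    produce the identical cohort.
    """
    config = config or CohortConfig.study_default()
    rng = np.random.default_rng(config.seed)
    records: list[ParticipantRecord] = []
    for stratum in config.strata:
        params = config.params_for(stratum.diagnosis)
        ages = _truncnorm_ages(rng, stratum.n, stratum.age_mean, stratum.age_sd)
        for i in range(stratum.n):
            transcript = _make_transcript(rng, config.reference_date, params.element_error_prob)
            score, _ = score_response(transcript, config.reference_date, rules="en")
            audio_seed = int(rng.integers(0, 2**31))
            record = ParticipantRecord(
                id=f"{stratum.facility}-{stratum.diagnosis[:3]}-{i:04d}",
                facility=stratum.facility,
                age=float(ages[i]),
                diagnosis=stratum.diagnosis,
                transcript=transcript,
                score=score.value,
                audio_seed=audio_seed,
            )
            if with_audio:
                record.audio = synthesize_response_audio(
                    params, duration_s=config.audio_duration_s, seed=audio_seed
                )
            records.append(record)
    return records


def cohort_frame(records: list[ParticipantRecord]) -> pd.DataFrame:
    """Tabular view of a cohort (id, facility, age, diagnosis, score, transcript)."""
    return pd.DataFrame(
        {
            "id": [r.id for r in records],
            "facility": [r.facility for r in records],
            "age": [r.age for r in records],
            "diagnosis": [r.diagnosis for r in records],
            "score": [r.score for r in records],
            "transcript": [r.transcript for r in records],
        }
    )


def featurize_cohort(
    records: list[ParticipantRecord], config: CohortConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Run the acoustic pipeline over a cohort and assemble (X, y).

    Audio is synthesized on demand from each record's stored
    ``audio_seed`` when not already attached, so large cohorts never
    hold all waveforms in memory at once.  Returns the (n, 22) feature
    matrix in canonical order and the diagnosis label vector.
    """
    from .acoustic_features import extract_features
    from .classifier import assemble_features

    X = np.empty((len(records), 22))
    y = np.empty(len(records), dtype=object)
    for i, record in enumerate(records):
        audio = record.audio
        if audio is None:
            if record.audio_seed is None:
                raise ConfigurationError(f"record {record.id} has neither audio nor audio_seed")
            audio = synthesize_response_audio(
                config.params_for(record.diagnosis),
                duration_s=config.audio_duration_s,
                seed=record.audio_seed,
            )
        acoustic = extract_features(audio)
        X[i] = assemble_features(record.age, record.score, acoustic)
        y[i] = record.diagnosis
    return X, y.astype(str)


# ---------------------------------------------------------------------------
# Exact predictions fixture from the published accuracy table
# ---------------------------------------------------------------------------

#: Printed metric fractions: facility -> {metric: (numerator, denominator, percent)}.
_PRINTED_TABLE = {
    "Total": {
        "accuracy": (1556, 1586, 98.1),
        "sensitivity": (476, 489, 97.3),
        "specificity": (1080, 1097, 98.5),
    },
    "A": {
        "accuracy": (765, 782, 97.8),
        "sensitivity": (279, 284, 98.2),
        "specificity": (486, 498, 97.6),
    },
    "B": {
        "accuracy": (735, 744, 98.8),
        "sensitivity": (182, 187, 97.3),
        "specificity": (553, 557, 99.3),
    },
    "C": {
        "accuracy": (56, 60, 93.3),
        "sensitivity": (15, 18, 83.3),
        "specificity": (41, 42, 97.6),
    },
}

#: Age moments per facility × diagnosis, reused for fixture ages.
_FIXTURE_AGE_MOMENTS = {
    (s.facility, s.diagnosis): (s.age_mean, s.age_sd) for s in STUDY_STRATA
}


def _facility_counts() -> dict[str, tuple[int, int, int, int]]:
    """Derive per-facility (tp, fn, fp, tn) from the printed fractions,
    cross-checking every derived cell against the printed table."""
    out = {}
    for fac in ("A", "B", "C"):
        row = _PRINTED_TABLE[fac]
        tp, n_pos, _ = row["sensitivity"]
        tn, n_neg, _ = row["specificity"]
        fn, fp = n_pos - tp, n_neg - tn
        n_correct, n_total, _ = row["accuracy"]
        if tp + tn != n_correct or n_pos + n_neg != n_total:
            raise ValidationError(f"facility {fac}: derived counts contradict printed fractions")
        for metric, (num, den, pct) in row.items():
            if percent_half_up(num, den) != pct:
                raise ValidationError(f"facility {fac} {metric}: {num}/{den} does not round to {pct}")
        out[fac] = (tp, fn, fp, tn)
    # pooled cells must match the printed totals
    pooled = tuple(sum(c[i] for c in out.values()) for i in range(4))
    tp, fn, fp, tn = pooled
    total = _PRINTED_TABLE["Total"]
    if (tp, tp + fn) != total["sensitivity"][:2] or (tn, fp + tn) != total["specificity"][:2]:
        raise ValidationError("pooled fixture counts contradict the printed totals")
    return out


def table2_fixture(seed: int = 0) -> pd.DataFrame:
    """Predictions table reproducing the published per-facility counts.

    Exactly 1586 rows (id, facility, age, true_label, predicted_label)
    whose confusion counts per facility are A:(279,5,12,486),
    B:(182,5,4,553), C:(15,3,1,41) as (tp, fn, fp, tn).  Counts — not
    individual assignments — are the contract; ages are drawn from the
    stratum age moments with the given seed, and misclassified rows are
    given ages >= 50 so the per-decade error profile stays plausible.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for fac, (tp, fn, fp, tn) in _facility_counts().items():
        cells = (
            (POSITIVE_LABEL, POSITIVE_LABEL, tp),
            (POSITIVE_LABEL, NEGATIVE_LABEL, fn),
            (NEGATIVE_LABEL, POSITIVE_LABEL, fp),
            (NEGATIVE_LABEL, NEGATIVE_LABEL, tn),
        )
        for true_label, predicted, count in cells:
            mean, sd = _FIXTURE_AGE_MOMENTS[(fac, true_label)]
            ages = _truncnorm_ages(rng, count, mean, sd)
            misclassified = true_label != predicted
            for age in ages:
                while misclassified and age < 50:
                    age = float(_truncnorm_ages(rng, 1, mean, sd)[0])
                rows.append((fac, float(age), true_label, predicted))
    df = pd.DataFrame(rows, columns=["facility", "age", "true_label", "predicted_label"])
    df.insert(0, "id", [f"p{i:04d}" for i in range(len(df))])
    return df
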