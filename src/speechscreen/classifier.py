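"""Gradient-boosting screening classifier over (age, score, acoustics).

The screening decision is a binary classification — dementia vs
cognitively normal — from a 22-dimensional feature vector in canonical
order: the speaker's age in years, the 0–4 time-orientation task score,
and the 20 low-order modulation-spectrum components (``ms_01..ms_20``).
Dementia is the positive class throughout, matching how sensitivity is
defined on the dementia group.

Ages outside [20, 100) are excluded from screening, mirroring the study
population's inclusion bounds.

No published trained model exists; the package trains on cohorts from
:mod:`speechscreen.synthetic`.  Default hyperparameters (300 trees,
depth 3, learning rate 0.05) are conservative choices for small tabular
problems and are fully configurable.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
from sklearn.ensemble import GradientBoostingClassifier

from .acoustic_features import ModSpecFeatures, N_COMPONENTS, acoustic_feature_names
from .errors import (
    AgeExclusionError,
    DegenerateTrainingError,
    DimensionError,
    ModelCompatibilityError,
    ValidationError,
)
from .orientation import TaskScore

POSITIVE_LABEL = "dementia"
NEGATIVE_LABEL = "cognitively_normal"
LABELS = (POSITIVE_LABEL, NEGATIVE_LABEL)

AGE_MIN, AGE_MAX = 20.0, 100.0  # [20, 100): the study's inclusion bounds

#: Canonical feature order: age first, then task score, then ms_01..ms_20.
FEATURE_NAMES: tuple[str, ...] = tuple(["age", "score"] + acoustic_feature_names(N_COMPONENTS))

MODEL_FORMAT_VERSION = 1


def check_age(age: float) -> float:
    """Validate the study age range [20, 100); raise AgeExclusionError otherwise."""
    if not np.isfinite(age) or not (AGE_MIN <= age < AGE_MAX):
        raise AgeExclusionError(
            f"age {age!r} outside the study range [{AGE_MIN:.0f}, {AGE_MAX:.0f})"
        )
    return float(age)


def assemble_features(
    age: float, score: TaskScore | int, acoustic: ModSpecFeatures | np.ndarray
) -> np.ndarray:
    """Build the canonical 22-vector (age, score, ms_01..ms_20).

    Raises
    ------
    AgeExclusionError
        If ``age`` is outside [20, 100).
    DimensionError
        If the acoustic part does not have exactly 20 components.
    ValidationError
        If the score is outside 0..4 or any value is non-finite.
    """
    age = check_age(age)
    score_value = score.value if isinstance(score, TaskScore) else int(score)
    TaskScore(score_value)  # range check
    acoustic_values = np.asarray(
        acoustic.components if isinstance(acoustic, ModSpecFeatures) else acoustic,
        dtype=np.float64,
    )
    if acoustic_values.shape != (N_COMPONENTS,):
        raise DimensionError(
            f"acoustic part must have exactly {N_COMPONENTS} components, "
            f"got shape {acoustic_values.shape}"
        )
    fv = np.concatenate([[age, float(score_value)], acoustic_values])
    if not np.all(np.isfinite(fv)):
        raise ValidationError("feature vector contains non-finite values")
    return fv


@dataclass(frozen=True)
class Hyperparams:
    """Gradient-boosting settings exposed to callers."""

    n_estimators: int = 300
    max_depth: int = 3
    learning_rate: float = 0.05
    subsample: float = 1.0


@dataclass
class ScreeningModel:
    """A fitted ensemble plus the metadata needed to apply it safely."""

    estimator: GradientBoostingClassifier
    hyperparams: Hyperparams
    feature_names: tuple[str, ...]
    seed: int
    threshold: float = 0.5

    def _check(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        if X.shape[1] != len(self.feature_names):
            raise DimensionError(
                f"feature vector length {X.shape[1]} does not match model "
                f"signature of {len(self.feature_names)} features"
            )
        return X

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Probability of dementia for each row of ``X``."""
        X = self._check(X)
        pos = list(self.estimator.classes_).index(1)
        return self.estimator.predict_proba(X)[:, pos]

    def predict(self, fv: np.ndarray) -> tuple[str, float]:
        """Label and dementia probability for one feature vector.

        The label is dementia iff probability >= threshold (inclusive at
        the boundary).
        """
        prob = float(self.predict_proba(fv)[0])
        label = POSITIVE_LABEL if prob >= self.threshold else NEGATIVE_LABEL
        return label, prob

    def predict_labels(self, X: np.ndarray) -> np.ndarray:
        probs = self.predict_proba(X)
        return np.where(probs >= self.threshold, POSITIVE_LABEL, NEGATIVE_LABEL)

    @property
    def feature_importances(self) -> np.ndarray:
        return self.estimator.feature_importances_


def train(
    X: np.ndarray,
    y: np.ndarray | list[str],
    hyperparams: Hyperparams | None = None,
    seed: int = 0,
    threshold: float = 0.5,
    min_per_class: int = 10,
) -> ScreeningModel:
    """Fit the screening classifier on labeled feature vectors.

    ``y`` holds string labels from {'dementia', 'cognitively_normal'}.
    Training is deterministic for fixed (X, y, hyperparams, seed).

    Raises
    ------
    DegenerateTrainingError
        If fewer than two classes are present or a class has fewer than
        ``min_per_class`` examples.
    ValidationError
        On unknown labels or non-finite features.
    """
    hyperparams = hyperparams or Hyperparams()
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2 or X.shape[1] != len(FEATURE_NAMES):
        raise DimensionError(
            f"X must be (n, {len(FEATURE_NAMES)}), got {X.shape}"
        )
    if not np.all(np.isfinite(X)):
        raise ValidationError("training features contain NaN or infinite values")
    y = np.asarray(y)
    unknown = set(np.unique(y)) - set(LABELS)
    if unknown:
        raise ValidationError(f"unknown labels: {sorted(unknown)}")
    y_bin = (y == POSITIVE_LABEL).astype(int)
    counts = np.bincount(y_bin, minlength=2)
    if (counts == 0).any():
        raise DegenerateTrainingError(
            f"need both classes present, got counts {dict(zip(LABELS[::-1], counts))}"
        )
    if (counts < min_per_class).any():
        raise DegenerateTrainingError(
            f"need >= {min_per_class} examples per class, got {counts.tolist()}"
        )
    estimator = GradientBoostingClassifier(
        n_estimators=hyperparams.n_estimators,
        max_depth=hyperparams.max_depth,
        learning_rate=hyperparams.learning_rate,
        subsample=hyperparams.subsample,
        random_state=seed,
    )
    estimator.fit(X, y_bin)
    return ScreeningModel(
        estimator=estimator,
        hyperparams=hyperparams,
        feature_names=FEATURE_NAMES,
        seed=seed,
        threshold=threshold,
    )


def save_model(model: ScreeningModel, path: str | Path) -> None:
    """Persist a model as a joblib binary plus a JSON metadata sidecar."""
    path = Path(path)
    joblib.dump(model.estimator, path)
    sidecar = {
        "format_version": MODEL_FORMAT_VERSION,
        "hyperparams": dataclasses.asdict(model.hyperparams),
        "feature_names": list(model.feature_names),
        "seed": model.seed,
        "threshold": model.threshold,
    }
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=2), encoding="utf-8"
    )


def load_model(path: str | Path) -> ScreeningModel:
    """Load a model saved by :func:`save_model`.

    Raises
    ------
    ModelCompatibilityError
        If the binary is corrupt/truncated, the sidecar is missing, or
        the format version does not match.
    """
    path = Path(path)
    sidecar_path = path.with_suffix(path.suffix + ".json")
    if not sidecar_path.exists():
        raise ModelCompatibilityError(f"missing model metadata sidecar: {sidecar_path}")
    try:
        meta = json.loads(sidecar_path.read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise ModelCompatibilityError(f"corrupt model metadata: {exc}") from exc
    if meta.get("format_version") != MODEL_FORMAT_VERSION:
        raise ModelCompatibilityError(
            f"model format version {meta.get('format_version')!r} != {MODEL_FORMAT_VERSION}"
        )
    try:
        estimator = joblib.load(path)
    except Exception as exc:
        raise ModelCompatibilityError(f"cannot load model binary {path}: {exc}") from exc
    return ScreeningModel(
        estimator=estimator,
        hyperparams=Hyperparams(**meta["hyperparams"]),
        feature_names=tuple(meta["feature_names"]),
        seed=int(meta["seed"]),
        threshold=float(meta["threshold"]),
    )
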