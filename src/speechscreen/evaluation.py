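"""Diagnostic-accuracy evaluation: confusion metrics and exact tests.

Given per-participant true diagnoses and predicted labels (dementia =
positive class), this module computes accuracy, sensitivity and
specificity with explicit numerators and denominators, stratified in
total, per facility, and per age decade, and tests the 2×2 and r×c
contingency tables with Fisher's exact conditional test.

Exact-test convention
---------------------
Two-sided p-values follow the probability-mass rule: conditional on the
observed margins, sum the (multivariate) hypergeometric probabilities of
every table whose probability does not exceed the observed table's
(within a small relative slack for ties).  This is the convention of the
classic R ``fisher.test`` implementation, and the r×c generalization is
computed by full enumeration of tables with the observed margins — cheap
here because error counts are small.  When the enumeration would exceed
a configured budget, a seeded Monte-Carlo estimate over random tables
with the same margins is available instead.

Percentages are rounded half-up to one decimal, the convention used when
reporting screening accuracy tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .classifier import AGE_MIN, AGE_MAX, LABELS, NEGATIVE_LABEL, POSITIVE_LABEL
from .errors import (
    AgeExclusionError,
    EnumerationBudgetError,
    ValidationError,
)

#: Relative slack when comparing table probabilities for the two-sided rule.
TIE_SLACK = 1e-7


# ---------------------------------------------------------------------------
# Confusion counts and metrics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConfusionCounts:
    """2×2 confusion counts with dementia as the positive class."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValidationError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    @property
    def n_positive(self) -> int:
        """Number of true dementia participants."""
        return self.tp + self.fn

    @property
    def n_negative(self) -> int:
        """Number of true cognitively normal participants."""
        return self.fp + self.tn

    def as_table(self) -> np.ndarray:
        """Diagnosis (rows) × prediction (cols) association table."""
        return np.array([[self.tp, self.fn], [self.fp, self.tn]], dtype=np.int64)


def _check_labels(labels: np.ndarray) -> None:
    unknown = set(np.unique(labels)) - set(LABELS)
    if unknown:
        raise ValidationError(f"unknown labels: {sorted(unknown)}; expected {LABELS}")


def confusion_counts(true_labels, predicted_labels) -> ConfusionCounts:
    """Count TP/FN/FP/TN from paired label vectors.

    Raises :class:`ValidationError` on length mismatch or labels outside
    {'dementia', 'cognitively_normal'}.
    """
    y_true = np.asarray(true_labels)
    y_pred = np.asarray(predicted_labels)
    if y_true.shape != y_pred.shape:
        raise ValidationError(
            f"label vectors differ in length: {y_true.shape} vs {y_pred.shape}"
        )
    _check_labels(y_true)
    _check_labels(y_pred)
    pos_t = y_true == POSITIVE_LABEL
    pos_p = y_pred == POSITIVE_LABEL
    return ConfusionCounts(
        tp=int(np.sum(pos_t & pos_p)),
        fn=int(np.sum(pos_t & ~pos_p)),
        fp=int(np.sum(~pos_t & pos_p)),
        tn=int(np.sum(~pos_t & ~pos_p)),
    )


def percent_half_up(numerator: int, denominator: int, decimals: int = 1) -> float:
    """100·numerator/denominator, rounded half-up to ``decimals`` places."""
    quantum = Decimal(1).scaleb(-decimals)
    value = Decimal(100 * numerator) / Decimal(denominator)
    return float(value.quantize(quantum, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class MetricValue:
    """A proportion reported as numerator/denominator and a percent.

    ``percent`` is ``None`` when the denominator is zero (undefined
    metric, reported as n/a rather than raising).
    """

    numerator: int
    denominator: int

    @property
    def percent(self) -> float | None:
        if self.denominator == 0:
            return None
        return percent_half_up(self.numerator, self.denominator)

    def __str__(self) -> str:
        if self.percent is None:
            return "n/a"
        return f"{self.percent:.1f}% ({self.numerator}/{self.denominator})"


@dataclass(frozen=True)
class Metrics:
    accuracy: MetricValue
    sensitivity: MetricValue
    specificity: MetricValue


def metrics(counts: ConfusionCounts) -> Metrics:
    """Accuracy, sensitivity and specificity with explicit fractions."""
    return Metrics(
        accuracy=MetricValue(counts.tp + counts.tn, counts.n),
        sensitivity=MetricValue(counts.tp, counts.n_positive),
        specificity=MetricValue(counts.tn, counts.n_negative),
    )


# ---------------------------------------------------------------------------
# Exact conditional tests
# ---------------------------------------------------------------------------


def _validate_table(table) -> np.ndarray:
    t = np.asarray(table)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise ValidationError(f"contingency table must be at least 2×2, got shape {t.shape}")
    if not np.issubdtype(t.dtype, np.integer):
        if not np.allclose(t, np.round(t)):
            raise ValidationError("contingency table cells must be integers")
        t = np.round(t).astype(np.int64)
    if (t < 0).any():
        raise ValidationError("contingency table cells must be non-negative")
    if t.sum() == 0:
        raise ValidationError("contingency table is empty")
    return t.astype(np.int64)


def _log_table_prob(table: np.ndarray, lgamma=math.lgamma) -> float:
    """Log multivariate hypergeometric probability of a table given its margins."""
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    n = table.sum()
    logp = (
        sum(lgamma(r + 1) for r in rows)
        + sum(lgamma(c + 1) for c in cols)
        - lgamma(n + 1)
        - sum(lgamma(x + 1) for x in table.flat)
    )
    return logp


def _enumerate_log_probs(rows: np.ndarray, cols: np.ndarray, max_tables: int):
    """Yield the log probability of every table with the given margins.

    Depth-first over cells in row-major order; the last cell of each row
    and the whole last row are forced by the margins.  Probabilities are
    accumulated incrementally as -sum(lgamma(cell+1)) plus the constant
    margin term.
    """
    r, c = len(rows), len(cols)
    const = (
        sum(math.lgamma(x + 1) for x in rows)
        + sum(math.lgamma(x + 1) for x in cols)
        - math.lgamma(rows.sum() + 1)
    )
    count = 0

    def rec(i: int, col_rem: tuple[int, ...], acc: float):
        nonlocal count
        if i == r - 1:
            # last row forced by remaining column totals
            count += 1
            if count > max_tables:
                raise EnumerationBudgetError(
                    f"exact enumeration exceeds budget of {max_tables} tables; "
                    "use method='monte-carlo'"
                )
            yield acc - sum(math.lgamma(x + 1) for x in col_rem)
            return
        # fill row i cell by cell; last cell forced by the row total
        def fill(j: int, row_rem: int, col_rem: tuple[int, ...], acc: float):
            if j == c - 1:
                if row_rem <= col_rem[j]:
                    new_cols = col_rem[:j] + (col_rem[j] - row_rem,)
                    yield from rec(i + 1, new_cols, acc - math.lgamma(row_rem + 1))
                return
            hi = min(row_rem, col_rem[j])
            for v in range(hi + 1):
                yield from fill(
                    j + 1,
                    row_rem - v,
                    col_rem[:j] + (col_rem[j] - v,) + col_rem[j + 1 :],
                    acc - math.lgamma(v + 1),
                )

        yield from fill(0, int(rows[i]), col_rem, acc)

    yield from rec(0, tuple(int(x) for x in cols), const)


def fisher_exact_rxc(
    table,
    method: str = "enumerate",
    max_tables: int = 2_000_000,
    n_mc: int = 100_000,
    seed: int = 0,
) -> float:
    """Two-sided exact conditional test of association in an r×c table.

    Conditional on the observed row and column totals, the p-value is
    the total multivariate-hypergeometric probability of all tables no
    more probable than the observed one (probability-mass two-sided
    rule).  ``method='enumerate'`` (default) enumerates every table with
    the observed margins and is exact; it raises
    :class:`EnumerationBudgetError` beyond ``max_tables`` tables, in
    which case ``method='monte-carlo'`` draws ``n_mc`` seeded random
    tables with the same margins instead.
    """
    t = _validate_table(table)
    rows, cols = t.sum(axis=1), t.sum(axis=0)
    if (rows == 0).any() or (cols == 0).any():
        # A zero margin means that category was never observed; drop it.
        t = t[rows > 0][:, cols > 0]
        if t.shape[0] < 2 or t.shape[1] < 2:
            return 1.0
        rows, cols = t.sum(axis=1), t.sum(axis=0)
    log_obs = _log_table_prob(t)
    cutoff = log_obs + math.log1p(TIE_SLACK)

    if method == "enumerate":
        total = 0.0
        for logp in _enumerate_log_probs(rows, cols, max_tables):
            if logp <= cutoff:
                total += math.exp(logp)
        return min(total, 1.0)
    if method == "monte-carlo":
        rng = np.random.default_rng(seed)
        # Sample tables from the conditional null by randomly pairing the
        # row and column category labels of the N individuals.
        row_labels = np.repeat(np.arange(len(rows)), rows)
        col_labels = np.repeat(np.arange(len(cols)), cols)
        hits = 0
        for _ in range(n_mc):
            perm = rng.permutation(col_labels)
            sim = np.zeros_like(t)
            np.add.at(sim, (row_labels, perm), 1)
            if _log_table_prob(sim) <= cutoff:
                hits += 1
        return (hits + 1) / (n_mc + 1)
    raise ValidationError(f"unknown method {method!r}; use 'enumerate' or 'monte-carlo'")


def fisher_exact_2x2(table, **kwargs) -> float:
    """Two-sided Fisher exact test on a 2×2 table (probability-mass rule).

    Runs through the same enumeration engine as :func:`fisher_exact_rxc`,
    of which it is the 2×2 specialization.
    """
    t = _validate_table(table)
    if t.shape != (2, 2):
        raise ValidationError(f"expected a 2×2 table, got shape {t.shape}")
    return fisher_exact_rxc(t, **kwargs)


# ---------------------------------------------------------------------------
# Stratified reporting
# ---------------------------------------------------------------------------

REQUIRED_COLUMNS = ("facility", "age", "true_label", "predicted_label")

DECADE_EDGES = np.arange(20, 101, 10)  # [20,30) ... [90,100)


def accuracy_by_age_decade(records: pd.DataFrame) -> pd.DataFrame:
    """Correct-classification rate per age decade and diagnosis group.

    Returns a frame with columns (decade, group, n, n_correct, percent),
    decades labelled by their lower bound (20 = ages 20–29, ...).  Empty
    strata are reported with n = 0 and percent = NaN.

    Raises :class:`AgeExclusionError` if any age falls outside [20, 100).
    """
    ages = records["age"].to_numpy(dtype=float)
    if ((ages < AGE_MIN) | (ages >= AGE_MAX)).any():
        bad = ages[(ages < AGE_MIN) | (ages >= AGE_MAX)]
        raise AgeExclusionError(f"ages outside [20, 100): {bad[:5].tolist()} ...")
    decade = (np.floor(ages / 10).astype(int) * 10).astype(int)
    correct = records["true_label"].to_numpy() == records["predicted_label"].to_numpy()
    out = []
    for group in (POSITIVE_LABEL, NEGATIVE_LABEL):
        in_group = records["true_label"].to_numpy() == group
        for lo in DECADE_EDGES[:-1]:
            mask = in_group & (decade == lo)
            n = int(mask.sum())
            n_correct = int((mask & correct).sum())
            out.append(
                {
                    "decade": int(lo),
                    "group": group,
                    "n": n,
                    "n_correct": n_correct,
                    "percent": percent_half_up(n_correct, n) if n else float("nan"),
                }
            )
    return pd.DataFrame(out)


@dataclass
class StratumResult:
    name: str
    counts: ConfusionCounts
    metrics: Metrics
    association_p: float  # 2×2 diagnosis-vs-prediction exact test


@dataclass
class EvaluationReport:
    """Full diagnostic-accuracy report over a predictions table."""

    total: StratumResult
    facilities: list[StratumResult]
    facility_accuracy_p: float | None
    facility_sensitivity_p: float | None
    facility_specificity_p: float | None
    by_age_decade: pd.DataFrame

    def to_dict(self) -> dict:
        def stratum(s: StratumResult) -> dict:
            return {
                "counts": {
                    "tp": s.counts.tp,
                    "fn": s.counts.fn,
                    "fp": s.counts.fp,
                    "tn": s.counts.tn,
                },
                "accuracy": _metric_dict(s.metrics.accuracy),
                "sensitivity": _metric_dict(s.metrics.sensitivity),
                "specificity": _metric_dict(s.metrics.specificity),
                "association_p": s.association_p,
            }

        return {
            "total": stratum(self.total),
            "facilities": {s.name: stratum(s) for s in self.facilities},
            "between_facility_p": {
                "accuracy": self.facility_accuracy_p,
                "sensitivity": self.facility_sensitivity_p,
                "specificity": self.facility_specificity_p,
            },
            "by_age_decade": self.by_age_decade.replace({float("nan"): None}).to_dict(
                orient="records"
            ),
        }

    def format_table(self) -> str:
        """Human-readable accuracy/sensitivity/specificity table."""
        lines = [f"{'':12s} {'Accuracy':>22s} {'Sensitivity':>22s} {'Specificity':>22s}"]
        for s in [self.total] + self.facilities:
            lines.append(
                f"{s.name:12s} {str(s.metrics.accuracy):>22s} "
                f"{str(s.metrics.sensitivity):>22s} {str(s.metrics.specificity):>22s}"
            )
        return "\n".join(lines)


def _metric_dict(m: MetricValue) -> dict:
    return {"numerator": m.numerator, "denominator": m.denominator, "percent": m.percent}


def _metric_table(strata: list[StratumResult], which: str) -> np.ndarray:
    """r×2 (correct, incorrect) table for one metric across facilities."""
    rows = []
    for s in strata:
        m: MetricValue = getattr(s.metrics, which)
        rows.append([m.numerator, m.denominator - m.numerator])
    return np.asarray(rows, dtype=np.int64)


def evaluate(records: pd.DataFrame) -> EvaluationReport:
    """Evaluate a predictions table (facility, age, true/predicted labels).

    Computes total and per-facility confusion metrics, the 2×2 exact
    association test per stratum, the between-facility r×c exact tests
    on correct/incorrect counts for each metric, and the per-age-decade
    correct-classification rates.
    """
    if len(records) == 0:
        raise ValidationError("empty predictions table")
    missing = [c for c in REQUIRED_COLUMNS if c not in records.columns]
    if missing:
        raise ValidationError(f"predictions table missing columns: {missing}")

    def stratum(name: str, df: pd.DataFrame) -> StratumResult:
        counts = confusion_counts(df["true_label"], df["predicted_label"])
        p = fisher_exact_2x2(counts.as_table()) if counts.n_positive and counts.n_negative else float("nan")
        return StratumResult(name=name, counts=counts, metrics=metrics(counts), association_p=p)

    total = stratum("Total", records)
    facilities = [
        stratum(str(fac), df)
        for fac, df in sorted(records.groupby("facility"), key=lambda kv: str(kv[0]))
    ]
    if len(facilities) >= 2:
        acc_p = fisher_exact_rxc(_metric_table(facilities, "accuracy"))
        sens_p = fisher_exact_rxc(_metric_table(facilities, "sensitivity"))
        spec_p = fisher_exact_rxc(_metric_table(facilities, "specificity"))
    else:
        acc_p = sens_p = spec_p = None
    return EvaluationReport(
        total=total,
        facilities=facilities,
        facility_accuracy_p=acc_p,
        facility_sensitivity_p=sens_p,
        facility_specificity_p=spec_p,
        by_age_decade=accuracy_by_age_decade(records),
    )
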