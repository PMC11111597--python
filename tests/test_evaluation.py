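"""Evaluation layer: confusion metrics with exact fractions, the exact
conditional contingency-table tests (against brute-force oracles and
scipy/R conventions), and stratified reporting."""

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from scipy.stats import fisher_exact as scipy_fisher

from speechscreen.errors import (
    AgeExclusionError,
    EnumerationBudgetError,
    ValidationError,
)
from speechscreen.evaluation import (
    ConfusionCounts,
    accuracy_by_age_decade,
    confusion_counts,
    evaluate,
    fisher_exact_2x2,
    fisher_exact_rxc,
    metrics,
    percent_half_up,
)
from speechscreen.synthetic import table2_fixture


# ---------------------------------------------------------------------------
# Brute-force oracles (exact rational arithmetic, coded independently)
# ---------------------------------------------------------------------------


def oracle_fisher_2x2(table):
    """Full enumeration over the free cell with Fraction probabilities."""
    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def prob(x):
        return Fraction(math.comb(r1, x) * math.comb(r2, c1 - x), math.comb(n, c1))

    p_obs = prob(a)
    total = sum(
        (p for x in range(max(0, c1 - r2), min(r1, c1) + 1) if (p := prob(x)) <= p_obs),
        Fraction(0),
    )
    return float(total)


def oracle_fisher_3x2(table):
    """Independent enumeration for 3×2 tables: loop the first column."""
    t = np.asarray(table)
    rows = t.sum(axis=1)
    c0 = t[:, 0].sum()
    n = t.sum()

    def prob(a0, a1, a2):
        num = math.comb(rows[0], a0) * math.comb(rows[1], a1) * math.comb(rows[2], a2)
        return Fraction(num, math.comb(n, c0))

    p_obs = prob(t[0, 0], t[1, 0], t[2, 0])
    total = Fraction(0)
    for a0 in range(min(rows[0], c0) + 1):
        for a1 in range(min(rows[1], c0 - a0) + 1):
            a2 = c0 - a0 - a1
            if 0 <= a2 <= rows[2]:
                p = prob(a0, a1, a2)
                if p <= p_obs:
                    total += p
    return float(total)


# ---------------------------------------------------------------------------
# Confusion counts and metrics
# ---------------------------------------------------------------------------


class TestConfusionCounts:
    def test_perfect_predictions(self):
        truth = ["dementia"] * 3 + ["cognitively_normal"] * 2
        counts = confusion_counts(truth, truth)
        assert (counts.tp, counts.fn, counts.fp, counts.tn) == (3, 0, 0, 2)

    def test_published_fixture_counts(self):
        df = table2_fixture()
        counts = confusion_counts(df["true_label"], df["predicted_label"])
        assert (counts.tp, counts.fn, counts.fp, counts.tn) == (476, 13, 17, 1080)

    def test_unknown_label_rejected(self):
        with pytest.raises(ValidationError):
            confusion_counts(["dementia"], ["unknown"])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            confusion_counts(["dementia"], ["dementia", "dementia"])

    def test_negative_counts_rejected(self):
        with pytest.raises(ValidationError):
            ConfusionCounts(tp=-1, fn=0, fp=0, tn=0)


class TestMetrics:
    def test_total_row(self):
        m = metrics(ConfusionCounts(tp=476, fn=13, fp=17, tn=1080))
        assert (m.accuracy.numerator, m.accuracy.denominator, m.accuracy.percent) == (1556, 1586, 98.1)
        assert (m.sensitivity.numerator, m.sensitivity.denominator, m.sensitivity.percent) == (476, 489, 97.3)
        assert (m.specificity.numerator, m.specificity.denominator, m.specificity.percent) == (1080, 1097, 98.5)

    def test_small_facility_row(self):
        m = metrics(ConfusionCounts(tp=15, fn=3, fp=1, tn=41))
        assert (m.accuracy.percent, m.sensitivity.percent, m.specificity.percent) == (93.3, 83.3, 97.6)
        assert str(m.accuracy) == "93.3% (56/60)"

    def test_empty_positive_stratum_is_na(self):
        m = metrics(ConfusionCounts(tp=0, fn=0, fp=0, tn=10))
        assert m.sensitivity.percent is None
        assert str(m.sensitivity) == "n/a"
        assert m.specificity.percent == 100.0

    def test_accuracy_decomposes_by_prevalence(self):
        rng = np.random.default_rng(0)
        labels = np.where(rng.random(200) < 0.3, "dementia", "cognitively_normal")
        preds = np.where(rng.random(200) < 0.5, "dementia", "cognitively_normal")
        c = metrics(confusion_counts(labels, preds))
        lhs = Fraction(c.accuracy.numerator, c.accuracy.denominator)
        rhs = (
            Fraction(c.sensitivity.numerator, 1) + Fraction(c.specificity.numerator, 1)
        ) / c.accuracy.denominator
        assert lhs == rhs

    def test_half_up_rounding(self):
        assert percent_half_up(1, 8) == 12.5
        assert percent_half_up(25, 1000) == 2.5
        assert percent_half_up(1845, 10000) == 18.5  # 18.45 rounds up, not to even


# ---------------------------------------------------------------------------
# Exact tests
# ---------------------------------------------------------------------------


class TestFisher2x2:
    def test_two_table_margins(self):
        """[[1,0],[0,1]]: both tables with these margins have p=1/2."""
        assert fisher_exact_2x2([[1, 0], [0, 1]]) == pytest.approx(1.0)

    def test_overall_association_highly_significant(self):
        assert fisher_exact_2x2([[476, 13], [17, 1080]]) < 0.001

    def test_matches_enumeration_oracle_on_random_tables(self):
        rng = np.random.default_rng(17)
        for _ in range(25):
            t = rng.integers(0, 9, size=(2, 2))
            if t.sum() == 0:
                continue
            assert fisher_exact_2x2(t) == pytest.approx(oracle_fisher_2x2(t), abs=1e-9)

    def test_matches_scipy_convention(self):
        rng = np.random.default_rng(23)
        for _ in range(15):
            t = rng.integers(0, 12, size=(2, 2))
            if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
                continue
            assert fisher_exact_2x2(t) == pytest.approx(scipy_fisher(t).pvalue, rel=1e-7)

    def test_symmetry_under_transpose_and_swaps(self):
        t = np.array([[7, 2], [3, 9]])
        p = fisher_exact_2x2(t)
        assert fisher_exact_2x2(t.T) == pytest.approx(p, abs=1e-12)
        assert fisher_exact_2x2(t[::-1]) == pytest.approx(p, abs=1e-12)
        assert fisher_exact_2x2(t[:, ::-1]) == pytest.approx(p, abs=1e-12)

    def test_negative_cell_rejected(self):
        with pytest.raises(ValidationError):
            fisher_exact_2x2([[1, -1], [0, 2]])


class TestFisherRxC:
    def test_facility_accuracy_table(self):
        """Correct/incorrect by facility: heterogeneity p rounds to 0.015."""
        table = [[765, 17], [735, 9], [56, 4]]
        p = fisher_exact_rxc(table)
        assert p == pytest.approx(oracle_fisher_3x2(table), abs=1e-9)
        assert round(p, 3) == 0.015

    def test_facility_sensitivity_table(self):
        table = [[279, 5], [182, 5], [15, 3]]
        p = fisher_exact_rxc(table)
        assert p == pytest.approx(oracle_fisher_3x2(table), abs=1e-9)
        assert round(p, 3) == 0.010

    def test_2x2_specialization_consistency(self):
        rng = np.random.default_rng(31)
        for _ in range(10):
            t = rng.integers(0, 10, size=(2, 2))
            if t.sum() == 0:
                continue
            assert fisher_exact_rxc(t) == fisher_exact_2x2(t)

    def test_small_3x3_against_r_reference(self):
        # R 4.3.3: fisher.test(matrix(c(3,1,2, 0,4,1, 2,2,5), nrow=3, byrow=TRUE)) -> 0.1799184
        assert fisher_exact_rxc([[3, 1, 2], [0, 4, 1], [2, 2, 5]]) == pytest.approx(
            0.1799183788, abs=1e-8
        )

    def test_budget_error_and_monte_carlo_fallback(self):
        table = [[765, 17], [735, 9], [56, 4]]
        with pytest.raises(EnumerationBudgetError):
            fisher_exact_rxc(table, max_tables=10)
        p_mc = fisher_exact_rxc(table, method="monte-carlo", n_mc=20000, seed=5)
        assert p_mc == pytest.approx(fisher_exact_rxc(table), abs=0.005)

    def test_zero_margin_categories_dropped(self):
        assert fisher_exact_rxc([[3, 0, 2], [1, 0, 4]]) == fisher_exact_2x2([[3, 2], [1, 4]])


# ---------------------------------------------------------------------------
# Stratified reporting
# ---------------------------------------------------------------------------


def _decade_fixture():
    rows = []
    # 4 dementia participants in their 40s, one misclassified
    rows += [("X", 44, "dementia", "dementia")] * 3
    rows += [("X", 47, "dementia", "cognitively_normal")]
    rows += [("X", 71, "cognitively_normal", "cognitively_normal")] * 5
    return pd.DataFrame(rows, columns=["facility", "age", "true_label", "predicted_label"])


class TestAgeDecades:
    def test_small_stratum_percent(self):
        report = accuracy_by_age_decade(_decade_fixture())
        row = report[(report.decade == 40) & (report.group == "dementia")].iloc[0]
        assert (row.n, row.n_correct, row.percent) == (4, 3, 75.0)

    def test_empty_bins_have_zero_n(self):
        report = accuracy_by_age_decade(_decade_fixture())
        row = report[(report.decade == 90) & (report.group == "dementia")].iloc[0]
        assert row.n == 0 and math.isnan(row.percent)

    def test_counts_add_up_on_published_fixture(self):
        df = table2_fixture()
        report = accuracy_by_age_decade(df)
        assert int(report.n_correct.sum()) == 1556
        assert int(report.n.sum()) == 1586

    def test_age_out_of_range_rejected(self):
        df = _decade_fixture()
        df.loc[0, "age"] = 101
        with pytest.raises(AgeExclusionError):
            accuracy_by_age_decade(df)


class TestEvaluateReport:
    def test_full_report_on_published_fixture(self):
        report = evaluate(table2_fixture())
        assert report.total.metrics.accuracy.percent == 98.1
        assert [s.name for s in report.facilities] == ["A", "B", "C"]
        assert report.facilities[1].metrics.accuracy.percent == 98.8
        assert round(report.facility_accuracy_p, 3) == 0.015
        assert round(report.facility_sensitivity_p, 3) == 0.010
        assert report.total.association_p < 0.001
        assert all(s.association_p < 0.001 for s in report.facilities)
        payload = report.to_dict()
        assert payload["facilities"]["C"]["sensitivity"]["percent"] == 83.3
        assert "93.3% (56/60)" in report.format_table()

    def test_missing_columns_rejected(self):
        with pytest.raises(ValidationError):
            evaluate(pd.DataFrame({"facility": ["A"], "age": [50]}))

    def test_empty_table_rejected(self):
        with pytest.raises(ValidationError):
            evaluate(pd.DataFrame(columns=["facility", "age", "true_label", "predicted_label"]))
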