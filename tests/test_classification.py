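"""Confusion-matrix arithmetic, report-table audits and the two-factor ANOVA."""

import numpy as np
import pytest

from endospectra.classification import (
    AnovaResult,
    ConfusionMatrix,
    aggregate,
    anova_two_factor_no_rep,
    metrics_from_confusion,
    round_half_away,
    weighted_accuracy_from_recalls,
)

#: Test-split class sizes of the emulated endoscopic dataset: normal,
#: staining, cancer, varicose, esophageal junction, inflammation,
#: duodenum, stomach.
TEST_SUPPORTS = np.array([20, 20, 40, 40, 20, 20, 20, 20])


def _random_cm(rng, n_classes=4, max_count=30):
    counts = rng.integers(0, max_count, (n_classes, n_classes))
    counts += np.diag(rng.integers(1, max_count, n_classes))
    return ConfusionMatrix([f"c{i}" for i in range(n_classes)], counts)


class TestMetrics:
    def test_hand_arithmetic_two_class(self):
        cm = ConfusionMatrix(["a", "b"], np.array([[8, 2], [4, 6]]))
        t = metrics_from_confusion(cm)
        np.testing.assert_allclose(t.precision, [8 / 12, 6 / 8])
        np.testing.assert_allclose(t.recall, [0.8, 0.6])
        assert t.accuracy == pytest.approx(0.7)
        np.testing.assert_allclose(
            t.f1, 2 * t.precision * t.recall / (t.precision + t.recall)
        )

    def test_diagonal_matrix_is_perfect(self):
        cm = ConfusionMatrix(["a", "b", "c"], np.diag([5, 7, 9]))
        t = metrics_from_confusion(cm)
        assert np.all(t.precision == 1.0) and np.all(t.recall == 1.0)
        assert np.all(t.f1 == 1.0) and t.accuracy == 1.0

    def test_never_predicted_class_gets_zero_precision(self):
        cm = ConfusionMatrix(["a", "b"], np.array([[5, 0], [5, 0]]))
        t = metrics_from_confusion(cm)
        assert t.precision[1] == 0.0 and t.f1[1] == 0.0

    def test_validation(self):
        with pytest.raises(ValueError):
            ConfusionMatrix(["a", "b"], np.array([[1, 2, 3], [4, 5, 6]]))
        with pytest.raises(ValueError):
            ConfusionMatrix(["a"], np.array([[-1]]))

    @pytest.mark.parametrize("seed", range(5))
    def test_accuracy_identity_with_recall_weighting(self, seed):
        cm = _random_cm(np.random.default_rng(seed))
        t = metrics_from_confusion(cm)
        assert weighted_accuracy_from_recalls(t.recall, t.supports) == pytest.approx(
            t.accuracy, abs=1e-15
        )

    def test_class_permutation_leaves_summaries_unchanged(self):
        cm = _random_cm(np.random.default_rng(42))
        t = metrics_from_confusion(cm)
        perm = np.random.default_rng(0).permutation(len(cm.classes))
        cm2 = ConfusionMatrix([cm.classes[i] for i in perm], cm.counts[np.ix_(perm, perm)])
        t2 = metrics_from_confusion(cm2)
        assert t2.accuracy == pytest.approx(t.accuracy)
        np.testing.assert_allclose(sorted(t2.f1), sorted(t.f1))
        assert aggregate(t2, "macro") == pytest.approx(aggregate(t, "macro"))
        assert aggregate(t2, "weighted") == pytest.approx(aggregate(t, "weighted"))


class TestReportTableAudits:
    """Audit printed per-class recall columns against their stated
    overall accuracies via accuracy = sum(n_c * recall_c) / N."""

    def test_logistic_regression_wli_column(self):
        # printed recalls: normal 0.45, staining 1.00, cancer 0.94,
        # varicose 0.93, junction/inflammation/duodenum/stomach 1.00
        recalls = [0.45, 1.00, 0.94, 0.93, 1.00, 1.00, 1.00, 1.00]
        acc = weighted_accuracy_from_recalls(recalls, TEST_SUPPORTS)
        assert acc == pytest.approx(0.919)
        assert round_half_away(100 * acc) == 92

    def test_mobilenet_wli_column(self):
        recalls = [0.95, 0.80, 0.85, 0.85, 0.90, 0.65, 0.95, 1.00]
        acc = weighted_accuracy_from_recalls(recalls, TEST_SUPPORTS)
        assert round_half_away(100 * acc, 1) == 86.5

    def test_mobilenet_nbi_column_is_internally_inconsistent(self):
        # the six printed NBI recalls imply 72% against the matching
        # supports, not the stated 75% -- the audit exposes, not fixes
        recalls = [0.80, 0.85, 0.76, 0.80, 0.80, 0.20]
        acc = weighted_accuracy_from_recalls(recalls, TEST_SUPPORTS[:6])
        assert round_half_away(100 * acc) == 72

    def test_perfect_recalls(self):
        assert weighted_accuracy_from_recalls(np.ones(8), TEST_SUPPORTS) == 1.0

    def test_yolo_save_macro_f1(self):
        f1 = np.array([0.82, 0.73, 0.86, 0.91, 0.80, 0.71, 1.00, 1.00])
        assert f1.mean() == pytest.approx(0.854, abs=5e-4)

    def test_argument_validation(self):
        with pytest.raises(ValueError):
            weighted_accuracy_from_recalls([0.5, 0.5], [10])
        with pytest.raises(ValueError):
            weighted_accuracy_from_recalls([0.5], [0])


class TestAggregate:
    def test_perfect_table_both_modes(self):
        cm = ConfusionMatrix(["a", "b"], np.diag([3, 9]))
        t = metrics_from_confusion(cm)
        assert aggregate(t, "macro") == (1.0, 1.0, 1.0)
        assert aggregate(t, "weighted") == (1.0, 1.0, 1.0)

    def test_equal_supports_macro_equals_weighted(self):
        cm = ConfusionMatrix(["a", "b"], np.array([[7, 3], [2, 8]]))
        t = metrics_from_confusion(cm)
        assert aggregate(t, "macro") == pytest.approx(aggregate(t, "weighted"))

    def test_unknown_mode(self):
        cm = ConfusionMatrix(["a", "b"], np.diag([1, 1]))
        with pytest.raises(ValueError):
            aggregate(metrics_from_confusion(cm), "micro")


def brute_force_anova(values):
    """Textbook double-loop sums of squares."""
    r, c = values.shape
    grand = values.sum() / values.size
    ss_rows = ss_cols = ss_total = 0.0
    for i in range(r):
        row_mean = sum(values[i]) / c
        ss_rows += (row_mean - grand) ** 2
    ss_rows *= c
    for j in range(c):
        col_mean = sum(values[:, j]) / r
        ss_cols += (col_mean - grand) ** 2
    ss_cols *= r
    for i in range(r):
        for j in range(c):
            ss_total += (values[i, j] - grand) ** 2
    return ss_rows, ss_cols, ss_total - ss_rows - ss_cols, ss_total


class TestAnova:
    def test_identical_columns_give_zero_column_effect(self):
        col = np.array([1.0, 4.0, 2.0, 8.0])
        res = anova_two_factor_no_rep(np.column_stack([col, col, col]))
        assert res.f_cols == 0.0
        assert res.p_cols == pytest.approx(1.0)

    def test_additive_table_has_zero_residual(self):
        table = np.arange(1.0, 10.0).reshape(3, 3)  # rows shift by +3
        res = anova_two_factor_no_rep(table)
        assert res.ss_residual == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_partition_matches_brute_force_on_16x3(self, seed):
        values = np.random.default_rng(seed).uniform(0, 100, (16, 3))
        res = anova_two_factor_no_rep(values)
        ssr, ssc, sse, sst = brute_force_anova(values)
        assert res.ss_rows == pytest.approx(ssr, abs=1e-9)
        assert res.ss_cols == pytest.approx(ssc, abs=1e-9)
        assert res.ss_residual == pytest.approx(sse, abs=1e-9)
        assert res.ss_total == pytest.approx(res.ss_rows + res.ss_cols + res.ss_residual,
                                             abs=1e-9)

    def test_matches_statsmodels_ols_decomposition(self):
        import pandas as pd
        import statsmodels.api as sm
        from statsmodels.formula.api import ols

        rng = np.random.default_rng(7)
        values = rng.uniform(60, 100, (6, 3))
        frame = pd.DataFrame(values).melt(ignore_index=False).reset_index()
        frame.columns = ["row", "col", "y"]
        fit = ols("y ~ C(row) + C(col)", data=frame).fit()
        table = sm.stats.anova_lm(fit, typ=2)
        res = anova_two_factor_no_rep(values)
        assert res.ss_rows == pytest.approx(table.loc["C(row)", "sum_sq"])
        assert res.ss_cols == pytest.approx(table.loc["C(col)", "sum_sq"])
        assert res.ss_residual == pytest.approx(table.loc["Residual", "sum_sq"])
        assert res.p_rows == pytest.approx(table.loc["C(row)", "PR(>F)"])
        assert res.p_cols == pytest.approx(table.loc["C(col)", "PR(>F)"])

    def test_f_invariant_to_constant_shift(self):
        values = np.random.default_rng(9).uniform(0, 1, (5, 4))
        a = anova_two_factor_no_rep(values)
        b = anova_two_factor_no_rep(values + 17.3)
        assert a.f_rows == pytest.approx(b.f_rows)
        assert a.f_cols == pytest.approx(b.f_cols)

    def test_column_summaries(self):
        values = np.random.default_rng(11).uniform(0, 1, (8, 3))
        res = anova_two_factor_no_rep(values, col_labels=["x", "y", "z"])
        np.testing.assert_allclose(res.col_means, values.mean(axis=0))
        np.testing.assert_allclose(res.col_sds, values.std(axis=0, ddof=1))
        assert res.col_labels == ["x", "y", "z"]

    def test_validation(self):
        with pytest.raises(ValueError):
            anova_two_factor_no_rep(np.ones((1, 3)))
        bad = np.ones((3, 3))
        bad[1, 1] = np.nan
        with pytest.raises(ValueError, match="complete"):
            anova_two_factor_no_rep(bad)
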