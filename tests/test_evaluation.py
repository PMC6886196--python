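"""Confusion matrices, exact binomial CI, per-class metrics, kappa."""

import math

import numpy as np
import pytest
from scipy.stats import binom
from sklearn.metrics import cohen_kappa_score

from pcomtext.evaluation import (
    CLASSES,
    ConfusionMatrix,
    accuracy_ci,
    agreement_report,
    cohens_kappa,
    confusion_matrix,
    evaluate_predictions,
    one_vs_rest_metrics,
)

# Published cross-classification of the two classifiers on 39,093 reports
# (rows: boosted trees; columns: rule-based), used as a fixed numeric fixture.
CROSSTAB = np.array([[17371, 5, 7], [0, 12311, 111], [3, 175, 9110]])


class TestConfusionMatrix:
    def test_identical_vectors_diagonal(self):
        m = confusion_matrix(["absent", "present"], ["absent", "present"])
        assert np.trace(m.counts) == m.total == 2

    def test_antidiagonal(self):
        m = confusion_matrix(["absent", "present"], ["present", "absent"])
        assert np.trace(m.counts) == 0
        assert m.total == 2

    def test_counts_sum_to_n(self):
        rng = np.random.default_rng(0)
        a = rng.choice(CLASSES, 1000)
        b = rng.choice(CLASSES, 1000)
        assert confusion_matrix(a, b).total == 1000

    def test_length_mismatch_and_unknown_label(self):
        with pytest.raises(ValueError):
            confusion_matrix(["absent"], ["absent", "present"])
        with pytest.raises(ValueError):
            confusion_matrix(["absent"], ["bogus"])


class TestAccuracyCI:
    @pytest.mark.parametrize(
        ("correct", "n", "low", "high"),
        [(961, 1000, 0.9471, 0.9721), (976, 1000, 0.9645, 0.9846)],
    )
    def test_published_bounds(self, correct, n, low, high):
        acc, lo, hi = accuracy_ci(correct, n)
        assert acc == correct / n
        assert round(lo, 4) == low
        assert round(hi, 4) == high

    def test_boundary_all_correct(self):
        _, _, hi = accuracy_ci(1000, 1000)
        assert hi == 1.0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            accuracy_ci(1, 0)
        with pytest.raises(ValueError):
            accuracy_ci(5, 3)

    def test_exact_interval_coverage(self):
        # 2000 seeded binomial draws at p=0.95, n=1000; the exact interval's
        # true coverage here is 0.9581, so the empirical rate should sit at
        # 0.95 or above up to Monte-Carlo error.
        rng = np.random.default_rng(2024)
        p, n, draws = 0.95, 1000, 2000
        ks = rng.binomial(n, p, size=draws)
        covered = 0
        for k in np.unique(ks):
            _, lo, hi = accuracy_ci(int(k), n)
            covered += int(lo <= p <= hi) * (ks == k).sum()
        mc_se = math.sqrt(0.95 * 0.05 / draws)
        assert covered / draws >= 0.95 - 1.96 * mc_se


class TestOneVsRest:
    def test_perfect_diagonal(self):
        m = ConfusionMatrix(CLASSES, np.diag([5, 3, 2]))
        for cls in CLASSES:
            metrics = one_vs_rest_metrics(m, cls)
            assert all(v == 1.0 for v in metrics.values())

    def test_hand_computed_collapse(self):
        m = ConfusionMatrix(CLASSES, np.array([[50, 5, 5], [4, 30, 6], [1, 4, 45]]))
        got = one_vs_rest_metrics(m, "absent")
        # collapse absent-vs-rest by hand: TP=50 FN=10 FP=5 TN=85
        assert got["sensitivity"] == pytest.approx(50 / 60)
        assert got["specificity"] == pytest.approx(85 / 90)
        assert got["ppv"] == pytest.approx(50 / 55)
        assert got["npv"] == pytest.approx(85 / 95)

    def test_missing_class_undefined_not_zero(self):
        m = ConfusionMatrix(CLASSES, np.array([[0, 0, 0], [0, 5, 0], [0, 0, 5]]))
        assert math.isnan(one_vs_rest_metrics(m, "absent")["sensitivity"])


class TestKappa:
    def test_published_crosstab_value(self):
        m = ConfusionMatrix(CLASSES, CROSSTAB)
        assert round(cohens_kappa(m), 4) == 0.9881
        assert round(cohens_kappa(m), 3) == 0.988

    def test_diagonal_is_one(self):
        assert cohens_kappa(ConfusionMatrix(CLASSES, np.diag([4, 5, 6]))) == 1.0

    def test_chance_agreement_is_zero(self):
        m = ConfusionMatrix(("absent", "present"), np.array([[10, 10], [10, 10]]))
        assert cohens_kappa(m) == pytest.approx(0.0)

    def test_matches_sklearn_on_random_labels(self):
        rng = np.random.default_rng(5)
        a = rng.choice(CLASSES, 500)
        b = np.where(rng.random(500) < 0.7, a, rng.choice(CLASSES, 500))
        ours = cohens_kappa(confusion_matrix(a, b))
        theirs = cohen_kappa_score(a, b)
        assert ours == pytest.approx(theirs, rel=1e-12)

    def test_permutation_invariance(self):
        perm = [2, 0, 1]
        m = ConfusionMatrix(CLASSES, CROSSTAB)
        permuted = ConfusionMatrix(
            tuple(CLASSES[i] for i in perm), CROSSTAB[np.ix_(perm, perm)]
        )
        assert cohens_kappa(m) == pytest.approx(cohens_kappa(permuted), rel=1e-12)

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            cohens_kappa(ConfusionMatrix(CLASSES, np.zeros((3, 3))))


class TestAgreementReport:
    def test_published_marginal_percentages(self):
        from pcomtext.evaluation import _report_from_matrix

        rep = _report_from_matrix(ConfusionMatrix(CLASSES, CROSSTAB), n_total=39093)
        assert [rep.marginals_b_pct[c] for c in CLASSES] == [44.4, 32.0, 23.6]
        assert [rep.marginals_a_pct[c] for c in CLASSES] == [44.5, 31.8, 23.8]
        assert round(rep.kappa, 4) == 0.9881

    def test_identical_predictions(self):
        preds = ["absent", "present", "unidentifiable", "absent"]
        rep = agreement_report(preds, preds)
        assert rep.kappa == 1.0
        assert rep.marginals_a == rep.marginals_b

    def test_marginals_recount(self):
        rng = np.random.default_rng(3)
        a = list(rng.choice(CLASSES, 400))
        b = list(rng.choice(CLASSES, 400))
        rep = agreement_report(a, b)
        for c in CLASSES:
            assert rep.marginals_a[c] == a.count(c)
            assert rep.marginals_b[c] == b.count(c)

    def test_accuracy_equals_trace_over_n(self):
        rng = np.random.default_rng(8)
        t = list(rng.choice(CLASSES, 300))
        p = list(np.where(rng.random(300) < 0.8, t, rng.choice(CLASSES, 300)))
        rep = evaluate_predictions(t, p)
        assert rep.accuracy == pytest.approx(np.trace(rep.matrix.counts) / 300)
        assert rep.ci_low <= rep.accuracy <= rep.ci_high
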