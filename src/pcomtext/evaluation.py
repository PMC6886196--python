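"""Agreement and accuracy statistics for three-way PCOM classification.

Confusion matrices (rows = rater/truth A, columns = rater/prediction B),
overall accuracy with an exact Clopper-Pearson binomial interval,
one-vs-rest sensitivity/specificity/PPV/NPV per class, Cohen's kappa,
and a two-classifier agreement report with marginal class percentages.
Undefined ratios (zero denominators) surface as NaN, never as 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "CLASSES",
    "ConfusionMatrix",
    "EvalReport",
    "confusion_matrix",
    "accuracy_ci",
    "one_vs_rest_metrics",
    "cohens_kappa",
    "evaluate_predictions",
    "agreement_report",
]

CLASSES = ("absent", "unidentifiable", "present")


@dataclass
class ConfusionMatrix:
    """K x K cross-tabulation over an ordered class list."""

    classes: tuple[str, ...]
    counts: np.ndarray  # rows: A / truth; columns: B / prediction

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        k = len(self.classes)
        if self.counts.shape != (k, k):
            raise ValueError("counts must be square and match the class list")
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def confusion_matrix(
    a_labels, b_labels, classes: tuple[str, ...] = CLASSES
) -> ConfusionMatrix:
    """Cross-tabulate two equal-length label sequences."""
    a = [str(x) for x in a_labels]
    b = [str(x) for x in b_labels]
    if len(a) != len(b):
        raise ValueError("label sequences must have equal length")
    index = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=np.int64)
    for ai, bi in zip(a, b):
        if ai not in index or bi not in index:
            raise ValueError(f"unknown label {ai!r} or {bi!r}")
        counts[index[ai], index[bi]] += 1
    return ConfusionMatrix(classes=tuple(classes), counts=counts)


def accuracy_ci(
    correct: int, n: int, level: float = 0.95
) -> tuple[float, float, float]:
    """Accuracy with the exact (Clopper-Pearson) binomial interval."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= correct <= n:
        raise ValueError("correct must lie in [0, n]")
    low, high = proportion_confint(correct, n, alpha=1 - level, method="beta")
    return correct / n, float(low), float(high)


def one_vs_rest_metrics(m: ConfusionMatrix, cls: str) -> dict[str, float]:
    """Sensitivity, specificity, PPV, NPV of one class against the rest.

    Rows of ``m`` are truth, columns prediction. Ratios with zero
    denominators are NaN.
    """
    i = m.classes.index(cls)
    tp = m.counts[i, i]
    fn = m.counts[i, :].sum() - tp
    fp = m.counts[:, i].sum() - tp
    tn = m.total - tp - fn - fp

    def ratio(num: int, den: int) -> float:
        return num / den if den > 0 else math.nan

    return {
        "sensitivity": ratio(tp, tp + fn),
        "specificity": ratio(tn, tn + fp),
        "ppv": ratio(tp, tp + fp),
        "npv": ratio(tn, tn + fn),
    }


def cohens_kappa(m: ConfusionMatrix) -> float:
    """Chance-corrected agreement (Po - Pe) / (1 - Pe) of a cross-tab.

    When expected agreement Pe is 1: defined as 1.0 if observed
    agreement is also 1, NaN otherwise.
    """
    n = m.total
    if n == 0:
        raise ValueError("empty matrix")
    po = np.trace(m.counts) / n
    pe = float((m.counts.sum(axis=1) * m.counts.sum(axis=0)).sum()) / n**2
    if pe == 1.0:
        return 1.0 if po == 1.0 else math.nan
    return (po - pe) / (1.0 - pe)


def _pct(count: int, total: int) -> float:
    """Percentage rounded half-up to one decimal, as printed in tables."""
    if total <= 0:
        return math.nan
    return float(
        (Decimal(count) * 100 / Decimal(total)).quantize(
            Decimal("0.1"), rounding=ROUND_HALF_UP
        )
    )


@dataclass
class EvalReport:
    """Bundle of accuracy, CI, per-class metrics and kappa."""

    matrix: ConfusionMatrix
    accuracy: float
    ci_low: float
    ci_high: float
    per_class: dict[str, dict[str, float]]
    kappa: float
    marginals_a: dict[str, int] = field(default_factory=dict)
    marginals_b: dict[str, int] = field(default_factory=dict)
    marginals_a_pct: dict[str, float] = field(default_factory=dict)
    marginals_b_pct: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "classes": list(self.matrix.classes),
            "counts": self.matrix.counts.tolist(),
            "accuracy": self.accuracy,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "per_class": self.per_class,
            "kappa": round(self.kappa, 4),
            "marginals_a": self.marginals_a,
            "marginals_b": self.marginals_b,
            "marginals_a_pct": self.marginals_a_pct,
            "marginals_b_pct": self.marginals_b_pct,
        }


def _report_from_matrix(m: ConfusionMatrix, n_total: int | None = None) -> EvalReport:
    n = m.total
    denom = n_total if n_total is not None else n
    correct = int(np.trace(m.counts))
    acc, lo, hi = accuracy_ci(correct, n)
    per_class = {c: one_vs_rest_metrics(m, c) for c in m.classes}
    row = m.counts.sum(axis=1)
    col = m.counts.sum(axis=0)
    return EvalReport(
        matrix=m,
        accuracy=acc,
        ci_low=lo,
        ci_high=hi,
        per_class=per_class,
        kappa=cohens_kappa(m),
        marginals_a={c: int(row[i]) for i, c in enumerate(m.classes)},
        marginals_b={c: int(col[i]) for i, c in enumerate(m.classes)},
        marginals_a_pct={c: _pct(int(row[i]), denom) for i, c in enumerate(m.classes)},
        marginals_b_pct={c: _pct(int(col[i]), denom) for i, c in enumerate(m.classes)},
    )


def evaluate_predictions(
    truth, predicted, classes: tuple[str, ...] = CLASSES
) -> EvalReport:
    """Score predictions against reference labels (rows = truth)."""
    return _report_from_matrix(confusion_matrix(truth, predicted, classes))


def agreement_report(
    pred_a,
    pred_b,
    n_total: int | None = None,
    classes: tuple[str, ...] = CLASSES,
) -> EvalReport:
    """Two-classifier agreement: cross-tab, kappa, marginal percentages.

    ``n_total`` sets the denominator for the marginal percentages (it
    defaults to the number of paired predictions).
    """
    return _report_from_matrix(confusion_matrix(pred_a, pred_b, classes), n_total)
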