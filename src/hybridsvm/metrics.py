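"""Imbalance-aware evaluation: confusion metrics, AUC, paired t-test, harness.

The positive class is the minority class throughout.  G-mean is the
geometric mean of sensitivity and specificity, so a classifier that never
predicts one of the classes scores exactly 0 no matter how high its raw
accuracy — the canonical failure mode on imbalanced clinical data.  Any
0/0 metric cell is defined as 0 and flagged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["ConfusionMatrix", "MetricSet", "TTestResult", "EvaluationReport",
           "confusion_from_predictions", "compute_metrics", "auc",
           "paired_t_test", "repeated_evaluate"]


@dataclass(frozen=True)
class ConfusionMatrix:
    """TP/FP/FN/TN counts with the minority class as positive."""

    TP: int
    FP: int
    FN: int
    TN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.FN, self.TN) < 0:
            raise ValueError("counts must be nonnegative")
        if self.n == 0:
            raise ValueError("empty confusion matrix")

    @property
    def n(self) -> int:
        return self.TP + self.FP + self.FN + self.TN


def confusion_from_predictions(y_true, y_pred) -> ConfusionMatrix:
    t = np.asarray(y_true, int)
    p = np.asarray(y_pred, int)
    if t.shape != p.shape:
        raise ValueError("length mismatch")
    return ConfusionMatrix(
        TP=int(np.sum((t == 1) & (p == 1))),
        FP=int(np.sum((t == 0) & (p == 1))),
        FN=int(np.sum((t == 1) & (p == 0))),
        TN=int(np.sum((t == 0) & (p == 0))),
    )


@dataclass(frozen=True)
class MetricSet:
    accuracy: float
    precision: float
    recall: float
    f1: float
    gmean: float
    degenerate: tuple[str, ...] = ()

    def as_dict(self) -> dict[str, float]:
        return {"accuracy": self.accuracy, "precision": self.precision,
                "recall": self.recall, "f1": self.f1, "gmean": self.gmean}


def _ratio(num: int, den: int, flags: list[str], name: str) -> float:
    if den == 0:
        flags.append(name)
        return 0.0
    return num / den


def compute_metrics(cm: ConfusionMatrix) -> MetricSet:
    """Accuracy, precision, recall, F1 and G-mean from a confusion matrix.

    G-mean = sqrt(TP/(TP+FN) * TN/(TN+FP)); F1 is the harmonic mean of
    precision and recall.  Undefined 0/0 ratios are 0 and listed in
    ``degenerate``.
    """
    flags: list[str] = []
    accuracy = (cm.TP + cm.TN) / cm.n
    precision = _ratio(cm.TP, cm.TP + cm.FP, flags, "precision")
    recall = _ratio(cm.TP, cm.TP + cm.FN, flags, "recall")
    specificity = _ratio(cm.TN, cm.TN + cm.FP, flags, "specificity")
    gmean = math.sqrt(recall * specificity)
    if precision + recall == 0:
        flags.append("f1")
        f1 = 0.0
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return MetricSet(accuracy, precision, recall, f1, gmean, tuple(flags))


def auc(y_true, scores) -> float:
    """Rank-based (Mann-Whitney) area under the ROC curve, ties counted 1/2.

    Equals the trapezoidal ROC area and the probability that a random
    positive outscores a random negative; invariant under strictly
    monotone transforms of the scores.
    """
    t = np.asarray(y_true, int)
    s = np.asarray(scores, float)
    if t.shape != s.shape:
        raise ValueError("length mismatch")
    n1 = int(np.sum(t == 1))
    n0 = int(np.sum(t == 0))
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(s)  # average ranks handle ties as 1/2
    r1 = float(np.sum(ranks[t == 1]))
    return (r1 - n1 * (n1 + 1) / 2) / (n1 * n0)


@dataclass(frozen=True)
class TTestResult:
    statistic: float
    pvalue: float
    df: int
    degenerate: bool = False


def paired_t_test(a, b) -> TTestResult:
    """Classical paired t-test (two-tailed) on per-repeat metric pairs.

    All-zero differences give (t=0, p=1); nonzero differences with zero
    variance give p=0 flagged degenerate (the statistic is unbounded).
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("sequences must be 1-D and equal length")
    n = a.size
    if n < 2:
        raise ValueError("need at least 2 pairs")
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        if np.allclose(d, 0.0):
            return TTestResult(0.0, 1.0, n - 1)
        return TTestResult(math.copysign(math.inf, d.mean()), 0.0, n - 1,
                           degenerate=True)
    t, p = stats.ttest_rel(a, b)
    return TTestResult(float(t), float(p), n - 1)


@dataclass
class EvaluationReport:
    """Per-repeat metric table and its column means."""

    per_repeat: pd.DataFrame
    artifacts: list = field(default_factory=list)

    @property
    def means(self) -> pd.Series:
        return self.per_repeat.mean(axis=0, numeric_only=True)

    def to_csv(self, path: str) -> None:
        self.per_repeat.to_csv(path, index=False)


def derive_seeds(master_seed: int, repeats: int) -> list[int]:
    """Deterministic per-repeat seeds below 2^31."""
    ss = np.random.SeedSequence(master_seed)
    return [int(s) % (2**31) for s in ss.generate_state(repeats)]


def repeated_evaluate(cfg, repeats: int = 10, master_seed: int = 0
                      ) -> EvaluationReport:
    """Run the full pipeline ``repeats`` times and average the metrics.

    Per-repeat seeds are derived deterministically from ``master_seed``;
    the report holds one metric row per repeat plus the run artifacts.
    """
    from .pipeline import run_pipeline  # deferred: pipeline imports metrics

    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    rows = []
    artifacts = []
    for r, seed in enumerate(derive_seeds(master_seed, repeats)):
        result = run_pipeline(cfg.with_seed(seed))
        row = {"repeat": r, "seed": seed, **result.metrics.as_dict(),
               "auc": result.auc}
        rows.append(row)
        artifacts.append(result)
    return EvaluationReport(pd.DataFrame(rows), artifacts)
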