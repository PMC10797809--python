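"""Multiclass evaluation: confusion counts, one-vs-rest rates, kappa, AUC.

Per-class rates are one-vs-rest: for class c, TP/FP/FN/TN are counted with c
as positive and all other classes pooled as negative, then

    precision   = TP / (TP + FP)
    recall      = TP / (TP + FN)
    specificity = TN / (TN + FP)
    F1          = 2·precision·recall / (precision + recall)

Rates with a zero denominator are *undefined*: they are reported as None,
excluded from macro averages, and logged — never silently substituted with 0.
Agreement beyond chance is unweighted Cohen's kappa; ranking quality is
one-vs-rest ROC AUC computed by the rank statistic (equivalent to trapezoidal
integration of the ROC curve, ties handled by mid-ranks), macro-averaged over
the classes present in the truth. A percentile bootstrap (resampling samples
with replacement) provides 95% intervals for any of these as generic
uncertainty plumbing.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.stats import rankdata

from .core import Frame

logger = logging.getLogger(__name__)

__all__ = [
    "ConfusionMatrix",
    "ClassRates",
    "MetricsReport",
    "confusion",
    "rates",
    "accuracy",
    "kappa",
    "auc_ovr",
    "evaluate",
    "bootstrap_ci",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """φ × φ count matrix; rows = true class, columns = predicted class."""

    frame: Frame
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.shape != (self.frame.size, self.frame.size):
            raise ValueError(
                f"counts must be {self.frame.size}x{self.frame.size}, got {counts.shape}"
            )
        if (counts < 0).any():
            raise ValueError("confusion counts must be non-negative")
        object.__setattr__(self, "counts", counts)
        counts.setflags(write=False)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def ovr_counts(self, label: str) -> tuple[int, int, int, int]:
        """(TP, FP, FN, TN) for ``label`` against the rest."""
        i = self.frame.index(label)
        tp = int(self.counts[i, i])
        fp = int(self.counts[:, i].sum()) - tp
        fn = int(self.counts[i, :].sum()) - tp
        tn = self.total - tp - fp - fn
        return tp, fp, fn, tn


@dataclass(frozen=True)
class ClassRates:
    precision: float | None
    recall: float | None
    specificity: float | None
    f1: float | None


def confusion(
    true_labels: Sequence[str],
    predicted_labels: Sequence[str],
    frame: Frame,
) -> ConfusionMatrix:
    """Count true-vs-predicted label pairs into a confusion matrix."""
    if len(true_labels) != len(predicted_labels):
        raise ValueError("true and predicted label sequences differ in length")
    counts = np.zeros((frame.size, frame.size), dtype=np.int64)
    for t, p in zip(true_labels, predicted_labels):
        counts[frame.index(str(t)), frame.index(str(p))] += 1
    return ConfusionMatrix(frame, counts)


def _ratio(num: int, den: int, what: str, label: str) -> float | None:
    if den == 0:
        logger.info("%s undefined for class %r (zero denominator)", what, label)
        return None
    return num / den


def rates(cm: ConfusionMatrix, label: str) -> ClassRates:
    """One-vs-rest precision, recall, specificity and F1 for one class.

    Undefined ratios (zero denominator) come back as None.
    """
    tp, fp, fn, tn = cm.ovr_counts(label)
    precision = _ratio(tp, tp + fp, "precision", label)
    recall = _ratio(tp, tp + fn, "recall", label)
    specificity = _ratio(tn, tn + fp, "specificity", label)
    if precision is None or recall is None or precision + recall == 0:
        if precision is not None and recall is not None:
            logger.info("f1 undefined for class %r (precision + recall = 0)", label)
        f1 = None
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return ClassRates(precision, recall, specificity, f1)


def accuracy(cm: ConfusionMatrix) -> float:
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return float(np.trace(cm.counts)) / cm.total


def kappa(cm: ConfusionMatrix) -> float | None:
    """Unweighted Cohen's kappa from the matrix marginals; None if p_e = 1."""
    n = cm.total
    if n == 0:
        raise ValueError("empty confusion matrix")
    p_o = np.trace(cm.counts) / n
    p_e = float(cm.counts.sum(axis=1) @ cm.counts.sum(axis=0)) / (n * n)
    if p_e >= 1.0:
        logger.info("kappa undefined: chance agreement p_e = 1")
        return None
    return float((p_o - p_e) / (1.0 - p_e))


def auc_ovr(
    true_labels: Sequence[str],
    score_matrix: np.ndarray,
    frame: Frame,
) -> tuple[dict[str, float], float | None]:
    """One-vs-rest ROC AUC per class and its unweighted macro average.

    AUC for class c is the Mann–Whitney rank statistic of the class-c scores
    of positives vs negatives (ties at mid-rank): the probability that a
    random positive outscores a random negative. Classes absent from the
    truth (or covering all of it) are skipped with a warning and excluded
    from the macro average.
    """
    scores = np.asarray(score_matrix, dtype=float)
    y = np.asarray([str(t) for t in true_labels])
    if scores.shape != (len(y), frame.size):
        raise ValueError(
            f"score matrix must be ({len(y)}, {frame.size}), got {scores.shape}"
        )
    per_class: dict[str, float] = {}
    for j, label in enumerate(frame.labels):
        pos = y == label
        n_pos = int(pos.sum())
        n_neg = len(y) - n_pos
        if n_pos == 0 or n_neg == 0:
            warnings.warn(
                f"class {label!r} has no {'positive' if n_pos == 0 else 'negative'} "
                "samples; skipped from AUC",
                stacklevel=2,
            )
            continue
        ranks = rankdata(scores[:, j])
        auc = (ranks[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
        per_class[label] = float(auc)
    macro = float(np.mean(list(per_class.values()))) if per_class else None
    return per_class, macro


def _macro(values: Sequence[float | None]) -> float | None:
    defined = [v for v in values if v is not None]
    return float(np.mean(defined)) if defined else None


@dataclass(frozen=True)
class MetricsReport:
    """Per-class and macro summaries of one evaluation run."""

    frame: Frame
    per_class: dict[str, ClassRates]
    macro_precision: float | None
    macro_recall: float | None
    macro_specificity: float | None
    macro_f1: float | None
    accuracy: float
    kappa: float | None
    auc_per_class: dict[str, float] = field(default_factory=dict)
    macro_auc: float | None = None
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "labels": list(self.frame.labels),
                "per_class": {
                    lab: vars(r).copy() for lab, r in self.per_class.items()
                },
                "macro_precision": self.macro_precision,
                "macro_recall": self.macro_recall,
                "macro_specificity": self.macro_specificity,
                "macro_f1": self.macro_f1,
                "accuracy": self.accuracy,
                "kappa": self.kappa,
                "auc_per_class": self.auc_per_class,
                "macro_auc": self.macro_auc,
                "ci": {k: list(v) for k, v in self.ci.items()},
            },
            indent=2,
        )


def evaluate(
    true_labels: Sequence[str],
    predicted_labels: Sequence[str],
    frame: Frame,
    score_matrix: np.ndarray | None = None,
) -> MetricsReport:
    """Full evaluation: confusion-derived rates, kappa, and (optionally) AUC."""
    cm = confusion(true_labels, predicted_labels, frame)
    per_class = {lab: rates(cm, lab) for lab in frame.labels}
    auc_pc: dict[str, float] = {}
    macro_auc = None
    if score_matrix is not None:
        auc_pc, macro_auc = auc_ovr(true_labels, score_matrix, frame)
    return MetricsReport(
        frame=frame,
        per_class=per_class,
        macro_precision=_macro([r.precision for r in per_class.values()]),
        macro_recall=_macro([r.recall for r in per_class.values()]),
        macro_specificity=_macro([r.specificity for r in per_class.values()]),
        macro_f1=_macro([r.f1 for r in per_class.values()]),
        accuracy=accuracy(cm),
        kappa=kappa(cm),
        auc_per_class=auc_pc,
        macro_auc=macro_auc,
    )


def bootstrap_ci(
    statistic: Callable[[np.ndarray], float],
    n_samples: int,
    n_replicates: int = 2000,
    level: float = 0.95,
    seed: int | None = None,
) -> tuple[float, float]:
    """Percentile bootstrap interval for ``statistic`` over sample indices.

    ``statistic`` receives an index array (a resample, with replacement, of
    ``range(n_samples)``) and returns the metric on that resample. Replicates
    where the statistic is undefined (None/NaN) are dropped.
    """
    rng = np.random.default_rng(seed)
    vals = []
    for _ in range(n_replicates):
        idx = rng.integers(0, n_samples, size=n_samples)
        v = statistic(idx)
        if v is not None and np.isfinite(v):
            vals.append(v)
    if not vals:
        raise ValueError("statistic undefined on every bootstrap replicate")
    lo, hi = np.percentile(vals, [100 * (1 - level) / 2, 100 * (1 + level) / 2])
    return float(lo), float(hi)
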