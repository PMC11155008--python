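"""Response labelling and classifier evaluation: accuracy, specificity,
recall, ROC/AUC with a stratified percentile-bootstrap 95% CI, and the 2x2
confusion matrix.

RECIST mapping: complete and partial response (CR, PR) are "responsive";
stable and progressive disease (SD, PD) are "nonresponsive".  The positive
class defaults to responsive (encoded 1) but every function takes a
``positive_label`` so either orientation can be reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import roc_auc_score, roc_curve

__all__ = [
    "map_recist",
    "roc_auc",
    "roc_points",
    "bootstrap_auc_ci",
    "paired_auc_diff_ci",
    "confusion_and_rates",
    "evaluate_scores",
    "MetricsReport",
]

RECIST_MAP = {"CR": 1, "PR": 1, "SD": 0, "PD": 0}
LABEL_NAMES = {1: "responsive", 0: "nonresponsive"}


def map_recist(category: str, as_name: bool = False) -> int | str:
    """Binary response label for a RECIST category (CR/PR -> 1, SD/PD -> 0)."""
    key = str(category).strip().upper()
    if key not in RECIST_MAP:
        raise ValueError(f"unknown RECIST category {category!r}; expected CR, PR, SD or PD")
    label = RECIST_MAP[key]
    return LABEL_NAMES[label] if as_name else label


def _check_scored(y_true: np.ndarray, scores: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y_true, dtype=int)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape or y.ndim != 1:
        raise ValueError("labels and scores must be matching 1-D arrays")
    if not np.all(np.isfinite(s)):
        raise ValueError("scores must be finite")
    return y, s


def roc_auc(y_true, scores, positive_label: int = 1) -> float:
    """Trapezoidal area under the ROC curve (ties contribute 1/2).

    Equivalent to the probability that a random positive is scored above a
    random negative, plus half the probability of a tie.
    """
    y, s = _check_scored(y_true, scores)
    if len(np.unique(y)) < 2:
        raise ValueError("AUC requires at least one sample of each class")
    return float(roc_auc_score((y == positive_label).astype(int), s))


def roc_points(y_true, scores, positive_label: int = 1):
    """(fpr, tpr, threshold) arrays of the empirical ROC curve."""
    y, s = _check_scored(y_true, scores)
    return roc_curve((y == positive_label).astype(int), s)


def _rank_auc(pos: np.ndarray, neg: np.ndarray) -> np.ndarray:
    """Row-wise AUC of positive-score rows vs negative-score rows via the
    Mann-Whitney rank identity (exact, ties counted half)."""
    from scipy.stats import rankdata

    n_pos, n_neg = pos.shape[1], neg.shape[1]
    ranks = rankdata(np.concatenate([neg, pos], axis=1), axis=1)
    rank_sum = ranks[:, n_neg:].sum(axis=1)
    return (rank_sum - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def bootstrap_auc_ci(
    y_true,
    scores,
    n_boot: int = 2000,
    level: float = 0.95,
    seed: int = 0,
    positive_label: int = 1,
) -> tuple[float, float]:
    """Stratified percentile bootstrap CI for the AUC.

    Patients are resampled with replacement within each class, which keeps
    the class counts fixed so every replicate has a defined AUC; replicate
    AUCs are computed by the rank identity, vectorised over replicates.
    Deterministic given ``seed``.
    """
    y, s = _check_scored(y_true, scores)
    ybin = (y == positive_label).astype(int)
    pos = s[ybin == 1]
    neg = s[ybin == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("bootstrap CI requires both classes")
    rng = np.random.default_rng(seed)
    pos_rs = rng.choice(pos, size=(n_boot, len(pos)))
    neg_rs = rng.choice(neg, size=(n_boot, len(neg)))
    aucs = _rank_auc(pos_rs, neg_rs)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(aucs, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def paired_auc_diff_ci(
    y_true,
    scores_a,
    scores_b,
    n_boot: int = 2000,
    level: float = 0.95,
    seed: int = 0,
    positive_label: int = 1,
) -> tuple[float, tuple[float, float]]:
    """AUC(a) - AUC(b) on a shared cohort, with a paired stratified
    bootstrap interval (patients resampled jointly for both score sets)."""
    y, sa = _check_scored(y_true, scores_a)
    _, sb = _check_scored(y_true, scores_b)
    diff = roc_auc(y, sa, positive_label) - roc_auc(y, sb, positive_label)
    ybin = (y == positive_label).astype(int)
    pos = np.flatnonzero(ybin == 1)
    neg = np.flatnonzero(ybin == 0)
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("paired bootstrap requires both classes")
    rng = np.random.default_rng(seed)
    pos_idx = rng.choice(pos, size=(n_boot, len(pos)))
    neg_idx = rng.choice(neg, size=(n_boot, len(neg)))
    diffs = _rank_auc(sa[pos_idx], sa[neg_idx]) - _rank_auc(sb[pos_idx], sb[neg_idx])
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(diffs, [alpha, 1.0 - alpha])
    return float(diff), (float(lo), float(hi))


@dataclass
class MetricsReport:
    """Threshold metrics plus ranking metrics for one scored cohort.

    ``confusion`` rows are true class (negative, positive), columns predicted
    class (negative, positive): ``[[TN, FP], [FN, TP]]``.
    """

    accuracy: float
    specificity: float
    recall: float
    auc: float | None = None
    auc_ci: tuple[float, float] | None = None
    confusion: np.ndarray = field(default_factory=lambda: np.zeros((2, 2), dtype=int))
    threshold: float = 0.5
    n: int = 0
    positive_label: int = 1

    def to_dict(self) -> dict:
        d = {
            "accuracy": self.accuracy,
            "specificity": self.specificity,
            "recall": self.recall,
            "auc": self.auc,
            "auc_ci": list(self.auc_ci) if self.auc_ci is not None else None,
            "confusion": np.asarray(self.confusion).tolist(),
            "threshold": self.threshold,
            "n": self.n,
            "positive_label": self.positive_label,
        }
        return d


def confusion_and_rates(
    y_true, scores, threshold: float = 0.5, positive_label: int = 1
) -> MetricsReport:
    """Threshold the scores (positive iff score >= threshold) and tabulate.

    accuracy = (TP+TN)/n, recall = TP/(TP+FN), specificity = TN/(TN+FP).
    An empty class leaves the corresponding rate NaN.
    """
    y, s = _check_scored(y_true, scores)
    if len(y) == 0:
        raise ValueError("cannot compute rates on an empty cohort")
    ybin = (y == positive_label).astype(int)
    pred = (s >= threshold).astype(int)
    cm = _sk_confusion(ybin, pred, labels=[0, 1])
    tn, fp, fn, tp = cm.ravel()
    acc = (tp + tn) / len(y)
    recall = tp / (tp + fn) if (tp + fn) else float("nan")
    spec = tn / (tn + fp) if (tn + fp) else float("nan")
    return MetricsReport(
        accuracy=float(acc),
        specificity=float(spec),
        recall=float(recall),
        confusion=cm,
        threshold=threshold,
        n=len(y),
        positive_label=positive_label,
    )


def evaluate_scores(
    y_true,
    scores,
    threshold: float = 0.5,
    positive_label: int = 1,
    n_boot: int = 2000,
    level: float = 0.95,
    seed: int = 0,
) -> MetricsReport:
    """Full report: threshold metrics plus AUC with bootstrap CI."""
    report = confusion_and_rates(y_true, scores, threshold, positive_label)
    y = np.asarray(y_true, dtype=int)
    if len(np.unique(y)) >= 2:
        report.auc = roc_auc(y_true, scores, positive_label)
        report.auc_ci = bootstrap_auc_ci(
            y_true, scores, n_boot=n_boot, level=level, seed=seed, positive_label=positive_label
        )
    return report
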