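"""Classifier evaluation: accuracy / F1 / AUROC, bootstrap confidence
intervals, and the paired tests used to compare models.

AUROC uses the rank (Mann–Whitney) formulation with ties counted half.
Confidence intervals are percentile bootstrap over sample-level resamples
(B = 1000 by default); resamples lacking one of the classes are redrawn.
The DeLong test compares two correlated AUROCs through the
structural-components covariance construction; the McNemar test compares
paired accuracies through discordant counts, exactly (two-sided binomial)
for small discordance and with a continuity-corrected chi-square
otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import binom, chi2, norm
from sklearn.metrics import accuracy_score, f1_score, roc_auc_score

from .core_data import ValidationError

__all__ = [
    "BinaryMetrics",
    "MetricsReport",
    "classification_metrics",
    "bootstrap_ci",
    "delong_test",
    "mcnemar_test",
    "metrics_report",
]

DEFAULT_THRESHOLD = 0.5
DEFAULT_BOOTSTRAP = 1000


@dataclass(frozen=True)
class BinaryMetrics:
    accuracy: float
    f1: float
    auroc: float


@dataclass
class MetricsReport:
    """Fold-wise and pooled metrics with 95% bootstrap CIs."""

    per_fold: list[BinaryMetrics]
    pooled: BinaryMetrics
    ci: dict[str, tuple[float, float]]
    n: int
    threshold: float
    ci_method: str = "percentile_bootstrap"

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "threshold": self.threshold,
            "ci_method": self.ci_method,
            "pooled": vars(self.pooled).copy(),
            "ci": {k: list(v) for k, v in self.ci.items()},
            "per_fold": [vars(m).copy() for m in self.per_fold],
        }


def _check_pair(labels, scores):
    labels = np.asarray(labels, dtype=np.int64)
    scores = np.asarray(scores, dtype=np.float64)
    if labels.shape != scores.shape or labels.ndim != 1:
        raise ValidationError("labels and scores must be 1-D and aligned")
    return labels, scores


def classification_metrics(labels, scores,
                           threshold: float = DEFAULT_THRESHOLD
                           ) -> BinaryMetrics:
    """Accuracy and responder-class F1 at ``threshold``; rank-based AUROC.

    AUROC requires both classes; F1 is for the positive (responder) class.
    """
    labels, scores = _check_pair(labels, scores)
    if len(np.unique(labels)) < 2:
        raise ValidationError("AUROC undefined: only one class present")
    preds = (scores >= threshold).astype(int)
    return BinaryMetrics(
        accuracy=float(accuracy_score(labels, preds)),
        f1=float(f1_score(labels, preds, zero_division=0.0)),
        auroc=float(roc_auc_score(labels, scores)))


def bootstrap_ci(labels, scores, metric: str = "auroc",
                 B: int = DEFAULT_BOOTSTRAP, seed: int = 0,
                 threshold: float = DEFAULT_THRESHOLD,
                 max_redraw_factor: int = 50) -> tuple[float, float]:
    """Percentile 2.5/97.5 interval over B seeded sample-level resamples.

    Resamples lacking a class are redrawn; if more than half the budget
    is exhausted by redraws, the metric is declared undefined.
    """
    labels, scores = _check_pair(labels, scores)
    if B < 100:
        raise ValidationError("B must be >= 100")
    if metric not in ("accuracy", "f1", "auroc"):
        raise ValidationError(f"unknown metric {metric!r}")
    rng = np.random.default_rng(seed)
    n = labels.size
    values: list[float] = []
    attempts = 0
    limit = max(2 * B, max_redraw_factor * B)
    while len(values) < B:
        attempts += 1
        if attempts - len(values) > limit // 2:
            raise ValidationError(
                f"metric undefined on more than half the resamples "
                f"({len(values)} valid of {attempts})")
        idx = rng.integers(0, n, n)
        lb, sc = labels[idx], scores[idx]
        if metric == "auroc":
            if len(np.unique(lb)) < 2:
                continue
            values.append(float(roc_auc_score(lb, sc)))
        else:
            preds = (sc >= threshold).astype(int)
            if metric == "accuracy":
                values.append(float(accuracy_score(lb, preds)))
            else:
                values.append(float(f1_score(lb, preds, zero_division=0.0)))
    return (float(np.percentile(values, 2.5)),
            float(np.percentile(values, 97.5)))


# ---------------------------------------------------------------------------
# DeLong test
# ---------------------------------------------------------------------------

def _midrank(x: np.ndarray) -> np.ndarray:
    order = np.argsort(x, kind="mergesort")
    ranks = np.empty(x.size)
    xs = x[order]
    i = 0
    while i < x.size:
        j = i
        while j < x.size and xs[j] == xs[i]:
            j += 1
        ranks[order[i:j]] = 0.5 * (i + j - 1) + 1
        i = j
    return ranks


def _structural_components(labels: np.ndarray, scores: np.ndarray
                           ) -> tuple[float, np.ndarray, np.ndarray]:
    """AUROC plus per-positive (V10) and per-negative (V01) components."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = pos.size, neg.size
    all_ranks = _midrank(np.concatenate([pos, neg]))
    pos_ranks = _midrank(pos)
    neg_ranks = _midrank(neg)
    auc = (all_ranks[:m].sum() - m * (m + 1) / 2) / (m * n)
    v10 = (all_ranks[:m] - pos_ranks) / n
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m
    return float(auc), v10, v01


def delong_test(labels, scores_a, scores_b) -> tuple[float, float]:
    """Paired comparison of two correlated AUROCs; returns (z, p).

    Zero covariance-weighted variance (identical scores) yields
    z = 0, p = 1 by convention.
    """
    labels, scores_a = _check_pair(labels, scores_a)
    _, scores_b = _check_pair(labels, scores_b)
    if len(np.unique(labels)) < 2:
        raise ValidationError("DeLong test needs both classes")
    auc_a, v10_a, v01_a = _structural_components(labels, scores_a)
    auc_b, v10_b, v01_b = _structural_components(labels, scores_b)
    m, n = v10_a.size, v01_a.size
    s10 = np.cov(np.stack([v10_a, v10_b]), ddof=1)
    s01 = np.cov(np.stack([v01_a, v01_b]), ddof=1)
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m \
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    if var <= 0:
        return 0.0, 1.0
    z = (auc_a - auc_b) / np.sqrt(var)
    p = 2 * norm.sf(abs(z))
    return float(z), float(p)


def mcnemar_test(labels, preds_a, preds_b,
                 exact_threshold: int = 25) -> float:
    """Paired accuracy comparison via discordant counts; returns p.

    b = samples A classifies correctly and B incorrectly; c the reverse.
    Exact two-sided binomial p when b+c ≤ ``exact_threshold``, else a
    continuity-corrected chi-square.  b + c = 0 gives p = 1.
    """
    labels = np.asarray(labels, dtype=np.int64)
    preds_a = np.asarray(preds_a, dtype=np.int64)
    preds_b = np.asarray(preds_b, dtype=np.int64)
    if not labels.shape == preds_a.shape == preds_b.shape:
        raise ValidationError("paired predictions must align with labels")
    right_a = preds_a == labels
    right_b = preds_b == labels
    b = int(np.sum(right_a & ~right_b))
    c = int(np.sum(~right_a & right_b))
    nd = b + c
    if nd == 0:
        return 1.0
    if nd <= exact_threshold:
        k = min(b, c)
        p = 2.0 * binom.cdf(k, nd, 0.5)
        if b == c:  # the center term would be counted twice
            p -= binom.pmf(k, nd, 0.5)
        return float(min(p, 1.0))
    stat = (abs(b - c) - 1) ** 2 / nd
    return float(chi2.sf(stat, df=1))


def metrics_report(fold_labels: list[np.ndarray],
                   fold_scores: list[np.ndarray],
                   threshold: float = DEFAULT_THRESHOLD,
                   B: int = DEFAULT_BOOTSTRAP, seed: int = 0
                   ) -> MetricsReport:
    """Fold-wise metrics plus pooled metrics with bootstrap CIs."""
    per_fold = [classification_metrics(lb, sc, threshold)
                for lb, sc in zip(fold_labels, fold_scores)]
    labels = np.concatenate(fold_labels)
    scores = np.concatenate(fold_scores)
    pooled = classification_metrics(labels, scores, threshold)
    ci = {m: bootstrap_ci(labels, scores, m, B=B, seed=seed,
                          threshold=threshold)
          for m in ("accuracy", "f1", "auroc")}
    return MetricsReport(per_fold, pooled, ci, labels.size, threshold)
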