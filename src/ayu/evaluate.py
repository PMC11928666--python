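"""Performance metrics for the localization classifiers.

Class imbalance (~10:1 cytoplasmic majority) makes accuracy misleading, so
the headline statistics are the k-category Matthews correlation coefficient
(Gorodkin's R_K, the covariance form computed from the confusion matrix) and
Cohen's kappa, complemented by per-class precision/recall and precision-
recall curves.  "unclassified" predictions are kept as an extra confusion
column: they count as false negatives for their true class but are never
false positives for any class (configurable to drop such rows instead).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import UNCLASSIFIED


@dataclass
class ConfusionMatrix:
    """counts[i, j] = items of true class i predicted as class j.  The
    optional last column holds unclassified predictions and is excluded from
    ``counts`` (the square matrix the correlation statistics use)."""

    counts: np.ndarray
    class_names: list[str]
    unclassified: np.ndarray | None = None

    @property
    def total(self) -> int:
        extra = 0 if self.unclassified is None else int(self.unclassified.sum())
        return int(self.counts.sum()) + extra


def confusion_and_prf(y_true, y_pred, class_names: list[str] | None = None,
                      unclassified_policy: str = "count"
                      ) -> tuple[ConfusionMatrix, dict]:
    """Confusion matrix plus per-class precision/recall.

    precision_c = TP/(TP+FP), recall_c = TP/(TP+FN); a zero denominator
    yields 0 and sets the class's ``zero_division`` flag.  With
    unclassified_policy="count" (default), unclassified predictions count
    against recall; with "drop" those rows are removed first.
    """
    y_true = np.asarray(y_true, dtype=object)
    y_pred = np.asarray(y_pred, dtype=object)
    if len(y_true) != len(y_pred):
        raise ValueError("label vectors differ in length")
    if unclassified_policy == "drop":
        keep = y_pred != UNCLASSIFIED
        y_true, y_pred = y_true[keep], y_pred[keep]
    elif unclassified_policy != "count":
        raise ValueError(f"unknown policy {unclassified_policy!r}")
    if class_names is None:
        class_names = sorted(set(y_true) | (set(y_pred) - {UNCLASSIFIED}))
    k = len(class_names)
    index = {c: i for i, c in enumerate(class_names)}
    counts = np.zeros((k, k), dtype=int)
    unclassified = np.zeros(k, dtype=int)
    for t, p in zip(y_true, y_pred):
        if p == UNCLASSIFIED:
            unclassified[index[t]] += 1
        else:
            counts[index[t], index[p]] += 1
    prf = {}
    for c, i in index.items():
        tp = counts[i, i]
        fp = counts[:, i].sum() - tp
        fn = counts[i, :].sum() - tp + unclassified[i]
        prf[c] = {
            "precision": float(tp / (tp + fp)) if tp + fp else 0.0,
            "recall": float(tp / (tp + fn)) if tp + fn else 0.0,
            "zero_division": bool(tp + fp == 0) or bool(tp + fn == 0),
        }
    return ConfusionMatrix(counts, list(class_names), unclassified), prf


def mcc_gorodkin(cm: np.ndarray) -> float:
    """k-category Matthews correlation coefficient (R_K).

    R_K = (N * tr(C) - sum_k t_k p_k) /
          sqrt((N^2 - sum_k p_k^2) * (N^2 - sum_k t_k^2))
    with t the true-class and p the predicted-class marginals.  A zero
    denominator (all mass in one row or one column) returns 0 by convention.
    For K = 2 this reduces exactly to the classical binary MCC.
    """
    cm = np.asarray(cm, dtype=float)
    if cm.size == 0 or cm.shape[0] != cm.shape[1] or cm.shape[0] < 2:
        raise ValueError("confusion matrix must be square, K >= 2")
    n = cm.sum()
    if n == 0:
        raise ValueError("empty confusion matrix")
    t = cm.sum(axis=1)
    p = cm.sum(axis=0)
    cov = n * np.trace(cm) - t @ p
    denom = np.sqrt(n * n - p @ p) * np.sqrt(n * n - t @ t)
    if denom == 0:
        return 0.0
    return float(cov / denom)


def cohen_kappa(cm: np.ndarray) -> float:
    """Cohen's kappa: (p_o - p_e) / (1 - p_e), chance agreement p_e from the
    marginals.  p_e = 1 (degenerate marginals) returns 0 by convention."""
    cm = np.asarray(cm, dtype=float)
    if cm.size == 0 or cm.shape[0] != cm.shape[1] or cm.shape[0] < 2:
        raise ValueError("confusion matrix must be square, K >= 2")
    n = cm.sum()
    if n == 0:
        raise ValueError("empty confusion matrix")
    p_o = np.trace(cm) / n
    p_e = (cm.sum(axis=1) @ cm.sum(axis=0)) / (n * n)
    if p_e == 1.0:
        return 0.0
    return float((p_o - p_e) / (1.0 - p_e))


def pr_curve(y_true: np.ndarray, scores: np.ndarray
             ) -> tuple[list[tuple[float, float]], float]:
    """Precision-recall curve over descending score thresholds plus average
    precision AP = sum_i (R_i - R_{i-1}) * P_i."""
    y_true = np.asarray(y_true, dtype=int)
    scores = np.asarray(scores, dtype=float)
    n_pos = int(y_true.sum())
    if n_pos == 0 or n_pos == len(y_true):
        raise ValueError("PR curve needs at least one positive and one negative")
    order = np.argsort(-scores, kind="stable")
    y_sorted = y_true[order]
    s_sorted = scores[order]
    tp = np.cumsum(y_sorted)
    fp = np.cumsum(1 - y_sorted)
    # evaluate only at the last index of each distinct threshold
    last = np.r_[s_sorted[1:] != s_sorted[:-1], True]
    tp, fp = tp[last], fp[last]
    precision = tp / (tp + fp)
    recall = tp / n_pos
    ap = 0.0
    prev_r = 0.0
    points = []
    for r, p in zip(recall, precision):
        ap += (r - prev_r) * p
        prev_r = r
        points.append((float(r), float(p)))
    return points, float(ap)


def group_importance(model, X_val: np.ndarray, y_val: np.ndarray,
                     layout: dict[str, slice], n_repeats: int = 5,
                     seed: int = 42) -> dict[str, dict[str, float]]:
    """Per-block feature importances for a trained localization model.

    gain / weight are read from the boosted-tree statistics and summed over
    each named block; permutation importance is the mean drop in k-category
    MCC over ``n_repeats`` shuffles of the whole block (columns permuted
    jointly, preserving within-block structure).
    """
    from .model import CLASS_NAMES, predict_with_threshold

    if max(s.stop for s in layout.values()) != model.n_features:
        raise ValueError("layout does not match the model's feature count")
    gain: dict[str, float] = {name: 0.0 for name in layout}
    weight: dict[str, float] = {name: 0.0 for name in layout}
    for learner in model.learners:
        booster = learner.get_booster()
        for itype, acc in (("gain", gain), ("weight", weight)):
            for feat, val in booster.get_score(importance_type=itype).items():
                col = int(feat[1:])  # features are named f<idx>
                for name, sl in layout.items():
                    if sl.start <= col < sl.stop:
                        acc[name] += val
                        break

    def score(Xe):
        calls, _ = predict_with_threshold(model, Xe, tau=0.0)
        truth = np.array([CLASS_NAMES[c] for c in np.asarray(y_val, dtype=int)])
        cm, _ = confusion_and_prf(truth, calls,
                                  class_names=list(CLASS_NAMES.values()))
        return mcc_gorodkin(cm.counts)

    X_val = np.asarray(X_val, dtype=float)
    base = score(X_val)
    rng = np.random.default_rng(seed)
    permutation: dict[str, float] = {}
    for name, sl in layout.items():
        drops = []
        for _ in range(n_repeats):
            Xp = X_val.copy()
            perm = rng.permutation(len(Xp))
            Xp[:, sl] = Xp[perm, sl]
            drops.append(base - score(Xp))
        permutation[name] = float(np.mean(drops))
    return {name: {"gain": gain[name], "weight": weight[name],
                   "permutation": permutation[name]}
            for name in layout}
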