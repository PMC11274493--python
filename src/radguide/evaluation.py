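"""Multi-class diagnostic performance: per-class sensitivity, specificity,
PPV and NPV via one-vs-rest collapse of the confusion matrix, plus
stratified and nested cross-validation utilities.

Evaluation covers the three patient classes (IPD, MSA, PSP); healthy
controls appear only in pretraining. Ratios with a zero denominator are
reported as missing (NaN), never as zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

PATIENT_CLASS_ORDER = ("IPD", "MSA", "PSP")


@dataclass
class ConfusionMatrix:
    counts: np.ndarray          # rows = true, columns = predicted
    class_order: tuple[str, ...]

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        k = len(self.class_order)
        if self.counts.shape != (k, k):
            raise ValueError("confusion matrix shape mismatch")
        if (self.counts < 0).any():
            raise ValueError("negative counts")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def accuracy(self) -> float:
        return float(np.trace(self.counts)) / self.total

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.class_order),
                            columns=list(self.class_order))


def confusion(true_labels, predicted_labels,
              class_order: tuple[str, ...] = PATIENT_CLASS_ORDER) -> ConfusionMatrix:
    t = list(true_labels)
    p = list(predicted_labels)
    if len(t) != len(p):
        raise ValueError("label vectors differ in length")
    unknown = (set(t) | set(p)) - set(class_order)
    if unknown:
        raise ValueError(f"label(s) outside class order: {sorted(unknown)}")
    k = len(class_order)
    idx = {c: i for i, c in enumerate(class_order)}
    counts = np.zeros((k, k), dtype=np.int64)
    for a, b in zip(t, p):
        counts[idx[a], idx[b]] += 1
    return ConfusionMatrix(counts=counts, class_order=tuple(class_order))


def _safe_ratio(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


def per_class_metrics(cm: ConfusionMatrix) -> pd.DataFrame:
    """Sensitivity / specificity / PPV / NPV per class (one-vs-rest)."""
    c = cm.counts
    total = c.sum()
    rows = {}
    for i, cls in enumerate(cm.class_order):
        tp = c[i, i]
        fn = c[i].sum() - tp
        fp = c[:, i].sum() - tp
        tn = total - tp - fn - fp
        rows[cls] = {
            "sensitivity": _safe_ratio(tp, tp + fn),
            "specificity": _safe_ratio(tn, tn + fp),
            "ppv": _safe_ratio(tp, tp + fp),
            "npv": _safe_ratio(tn, tn + fn),
        }
    return pd.DataFrame(rows).T


def metrics_from_labels(true_labels, predicted_labels,
                        class_order: tuple[str, ...] = PATIENT_CLASS_ORDER) -> pd.DataFrame:
    return per_class_metrics(confusion(true_labels, predicted_labels, class_order))


def stratified_kfold(labels, k: int = 5, seed: int = 0) -> np.ndarray:
    """Deterministic stratified fold assignment (0..k-1 per subject)."""
    y = np.asarray(list(labels))
    values, counts = np.unique(y, return_counts=True)
    small = values[counts < k]
    if len(small):
        raise ValueError(f"class(es) smaller than k={k}: {list(small)}")
    cv = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = np.empty(len(y), dtype=np.int64)
    for f, (_, test_idx) in enumerate(cv.split(np.zeros(len(y)), y)):
        folds[test_idx] = f
    return folds


def nested_cv(features, labels, fit_fn, score_fn, param_grid,
              outer_k: int = 5, inner_k: int = 5, seed: int = 0):
    """Generic nested cross-validation.

    ``fit_fn(x_train, y_train, param) -> model`` and
    ``score_fn(model, x_test, y_test) -> float`` (higher better). The inner
    loop selects the parameter per outer fold; outer folds never influence
    selection. Returns (per-fold chosen parameters, per-fold outer scores).
    """
    x = np.asarray(features, dtype=np.float64)
    y = np.asarray(list(labels))
    outer = stratified_kfold(y, outer_k, seed)
    chosen, scores = [], []
    for f in range(outer_k):
        tr = outer != f
        te = ~tr
        inner = stratified_kfold(y[tr], inner_k, seed + 1000 + f)
        best_p, best_s = None, -np.inf
        for p in param_grid:
            s = 0.0
            for g in range(inner_k):
                itr = inner != g
                ite = ~itr
                model = fit_fn(x[tr][itr], y[tr][itr], p)
                s += score_fn(model, x[tr][ite], y[tr][ite])
            if s > best_s:
                best_p, best_s = p, s
        model = fit_fn(x[tr], y[tr], best_p)
        scores.append(score_fn(model, x[te], y[te]))
        chosen.append(best_p)
    return chosen, np.asarray(scores)
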