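"""Cross-validated evaluation: confusion matrices and macro precision/recall.

Convention used throughout (and in the serialized CSV form): confusion-matrix
ROWS are the estimated labels, COLUMNS the known labels.  Per-class precision
is therefore diagonal / row sum and recall diagonal / column sum; macro
scores are unweighted means over classes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from fractions import Fraction

import numpy as np

from . import discriminant, preprocess, svm

__all__ = ["ConfusionMatrix", "precision_recall", "summarize", "kfold_evaluate",
           "stratified_folds"]


class EvaluationError(ValueError):
    pass


@dataclass
class ConfusionMatrix:
    """c x c integer counts; rows = estimated labels, columns = known labels."""

    counts: np.ndarray
    class_order: list

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        c = len(self.class_order)
        if self.counts.shape != (c, c):
            raise EvaluationError(
                f"counts shape {self.counts.shape} does not match "
                f"{c} classes"
            )
        if np.any(self.counts < 0) or not np.issubdtype(self.counts.dtype, np.integer):
            raise EvaluationError("counts must be non-negative integers")

    @classmethod
    def from_predictions(cls, y_true, y_pred, class_order=None) -> "ConfusionMatrix":
        if class_order is None:
            class_order = sorted(set(y_true) | set(y_pred))
        index = {lab: i for i, lab in enumerate(class_order)}
        c = len(class_order)
        counts = np.zeros((c, c), dtype=int)
        for t, p in zip(y_true, y_pred, strict=True):
            counts[index[p], index[t]] += 1
        return cls(counts=counts, class_order=list(class_order))

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def misclassified(self) -> int:
        """Number of evaluated measurements off the diagonal."""
        return int(self.counts.sum() - np.trace(self.counts))

    def transpose(self) -> "ConfusionMatrix":
        return ConfusionMatrix(self.counts.T.copy(), list(self.class_order))


def _truncate_if_nonterminating(tp: int, denom: int) -> float:
    """Per-class ratio with 2-decimal truncation of non-terminating decimals.

    A reduced fraction has a terminating decimal expansion iff its
    denominator factors into 2s and 5s only; those are returned exactly,
    anything else is truncated (floored) at two decimal places.  This
    reproduces by-hand arithmetic that writes 7/9 as 0.77 but keeps 5/8
    as 0.625 before averaging.
    """
    frac = Fraction(tp, denom)
    d = frac.denominator
    for f in (2, 5):
        while d % f == 0:
            d //= f
    if d == 1:
        return float(frac)
    return float(Fraction(int(frac * 100), 100))


def precision_recall(
    confusion: ConfusionMatrix, rounding_mode: str = "exact",
    skip_undefined: bool = False,
):
    """Macro precision, macro recall and the per-class values.

    ``rounding_mode="paper"`` truncates each non-terminating per-class ratio
    to two decimals before averaging (hand-calculation convention);
    ``"exact"`` (default) averages the exact ratios.  A class never predicted
    (empty row) gets precision 0 with a warning, or is dropped from the macro
    mean if ``skip_undefined``.  A class absent from the known labels (empty
    column) makes recall undefined and raises.

    Returns ``(macro_precision, macro_recall, per_class)`` with ``per_class``
    a dict ``label -> {"precision": .., "recall": ..}``.
    """
    if rounding_mode not in ("exact", "paper"):
        raise EvaluationError(f"unknown rounding_mode {rounding_mode!r}")
    counts = confusion.counts
    row_sums = counts.sum(axis=1)
    col_sums = counts.sum(axis=0)
    per_class: dict = {}
    precisions, recalls = [], []
    for i, lab in enumerate(confusion.class_order):
        tp = int(counts[i, i])
        if col_sums[i] == 0:
            raise EvaluationError(
                f"recall undefined: class {lab!r} has no known-label instances"
            )
        if row_sums[i] == 0:
            warnings.warn(
                f"class {lab!r} was never predicted; precision set to 0",
                stacklevel=2,
            )
            if not skip_undefined:
                precisions.append(0.0)
            p_val = 0.0
        else:
            p_val = (
                _truncate_if_nonterminating(tp, int(row_sums[i]))
                if rounding_mode == "paper"
                else tp / int(row_sums[i])
            )
            precisions.append(p_val)
        r_val = (
            _truncate_if_nonterminating(tp, int(col_sums[i]))
            if rounding_mode == "paper"
            else tp / int(col_sums[i])
        )
        recalls.append(r_val)
        per_class[lab] = {"precision": p_val, "recall": r_val}
    macro_p = float(np.mean(precisions)) if precisions else float("nan")
    macro_r = float(np.mean(recalls))
    return macro_p, macro_r, per_class


def summarize(confusion: ConfusionMatrix) -> dict:
    """Report record: per-class TP/FP/FN, misclassification count, macro P/R."""
    counts = confusion.counts
    macro_p, macro_r, per_class = precision_recall(confusion)
    report = {
        "classes": list(confusion.class_order),
        "total": confusion.total,
        "misclassified": confusion.misclassified(),
        "macro_precision": macro_p,
        "macro_recall": macro_r,
        "per_class": {},
        "confusion": counts.tolist(),
    }
    for i, lab in enumerate(confusion.class_order):
        tp = int(counts[i, i])
        report["per_class"][lab] = {
            "tp": tp,
            "fp": int(counts[i].sum() - tp),
            "fn": int(counts[:, i].sum() - tp),
            **per_class[lab],
        }
    return report


def stratified_folds(labels, k: int, seed: int = 0) -> list[np.ndarray]:
    """Split indices into k folds, balancing every class across folds.

    Each class's indices are shuffled (seeded) and dealt round-robin,
    starting from a rotating fold offset so small classes do not all land in
    the low-numbered folds.  With classes of 8-9 members and k = 10 this
    leaves every training split with at least c - 1 members per class.
    """
    labels = list(labels)
    M = len(labels)
    if k < 2:
        raise EvaluationError(f"k must be >= 2, got {k}")
    if k > M:
        raise EvaluationError(f"k = {k} exceeds the {M} measurements")
    rng = np.random.default_rng(seed)
    by_class: dict = {}
    for i, lab in enumerate(labels):
        by_class.setdefault(lab, []).append(i)
    folds: list[list[int]] = [[] for _ in range(k)]
    offset = 0
    for lab in by_class:
        idx = np.array(by_class[lab])
        rng.shuffle(idx)
        for j, i in enumerate(idx):
            folds[(offset + j) % k].append(int(i))
        offset += len(idx)
    return [np.array(sorted(f), dtype=int) for f in folds if f]


def _merge_incomplete_folds(folds: list[np.ndarray], labels) -> list[np.ndarray]:
    """Merge any fold whose removal would empty a class out of training."""
    labels = np.asarray(labels, dtype=object)
    classes = set(labels)
    out = list(folds)
    i = 0
    while i < len(out):
        train = np.concatenate([f for j, f in enumerate(out) if j != i])
        if set(labels[train]) == classes:
            i += 1
            continue
        if len(out) <= 2:
            raise EvaluationError(
                "a class has too few members to appear in every training split"
            )
        warnings.warn(
            "a class would vanish from the training folds; merging the "
            "affected fold with its neighbour",
            stacklevel=2,
        )
        nxt = (i + 1) % len(out)
        merged = np.sort(np.concatenate([out[i], out[nxt]]))
        out = [f for j, f in enumerate(out) if j not in (i, nxt)]
        out.insert(min(i, nxt), merged)
        i = 0
    return out


def kfold_evaluate(
    raw_responses: np.ndarray,
    labels,
    k: int = 10,
    seed: int = 0,
    variance: float = 0.90,
    p: int | None = None,
    q: int | None = None,
    penalty: float = 1.0,
    kernel: str = "linear",
    gamma: float | None = None,
    global_scaling: bool = False,
) -> ConfusionMatrix:
    """Stratified k-fold cross-validation of the full reduction pipeline.

    ``raw_responses`` is the M x N matrix of smoothed dR/R responses BEFORE
    autoscaling: for each fold, autoscaling statistics, the EigenOdour basis,
    the LDA projection and the SVM are fitted on the training folds only and
    applied to the held-out fold (``global_scaling=True`` instead autoscales
    once on all data — the laxer protocol some studies leave implicit).
    Aggregated held-out predictions fill the confusion matrix, whose class
    order is first-occurrence order of ``labels``.
    """
    X = np.asarray(raw_responses, dtype=float)
    labels = list(labels)
    if X.shape[0] != len(labels):
        raise EvaluationError(f"{len(labels)} labels for {X.shape[0]} rows")
    class_order = list(dict.fromkeys(labels))
    folds = stratified_folds(labels, k, seed)
    folds = _merge_incomplete_folds(folds, labels)

    if global_scaling:
        scaled_all = preprocess.autoscale(X)

    y_true: list = []
    y_pred: list = []
    for test_idx in folds:
        train_idx = np.setdiff1d(np.arange(X.shape[0]), test_idx)
        train_labels = [labels[i] for i in train_idx]
        if global_scaling:
            Xtr = scaled_all.values[train_idx]
            Xte = scaled_all.values[test_idx]
        else:
            rm = preprocess.autoscale(X[train_idx], labels=train_labels)
            Xtr = rm.values
            Xte = rm.apply(X[test_idx])
        model = discriminant.fit_discriminant(
            Xtr, train_labels, p=p, q=q, variance=variance
        )
        Ztr = discriminant.transform(model, Xtr)
        Zte = discriminant.transform(model, Xte)
        clf = svm.fit_crammer_singer(
            Ztr, train_labels, penalty=penalty, kernel=kernel, gamma=gamma
        )
        preds = svm.predict(clf, Zte)
        y_pred.extend(preds)
        y_true.extend(labels[i] for i in test_idx)

    return ConfusionMatrix.from_predictions(y_true, y_pred, class_order)
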