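"""Confusion-matrix bookkeeping, macro precision/recall, k-fold CV."""

import numpy as np
import pytest

from enosekit import evaluate
from enosekit.benchmarks import background_series_confusion, mixture_series_confusion
from enosekit.evaluate import ConfusionMatrix, EvaluationError


class TestConfusionMatrix:
    def test_from_predictions_orientation(self):
        # rows = estimated labels, columns = known labels
        cm = ConfusionMatrix.from_predictions(
            y_true=["a", "a", "b"], y_pred=["a", "b", "b"],
            class_order=["a", "b"],
        )
        assert cm.counts.tolist() == [[1, 0], [1, 1]]
        assert cm.total == 3

    def test_negative_or_float_counts_rejected(self):
        with pytest.raises(EvaluationError):
            ConfusionMatrix(np.array([[1, -1], [0, 1]]), ["a", "b"])
        with pytest.raises(EvaluationError):
            ConfusionMatrix(np.ones((2, 2)), ["a", "b"])

    def test_misclassified_counts_off_diagonal(self):
        assert mixture_series_confusion().misclassified() == 5
        assert background_series_confusion().misclassified() == 0


class TestPrecisionRecall:
    def test_mixture_series_macro_precision(self):
        # per-class 8/8, 8/10, 7/10, 5/5, 8/8 -> macro 0.9
        P, _, _ = evaluate.precision_recall(mixture_series_confusion())
        assert P == pytest.approx(0.9)

    def test_mixture_series_macro_recall_both_rounding_modes(self):
        cm = mixture_series_confusion()
        _, R_paper, _ = evaluate.precision_recall(cm, rounding_mode="paper")
        # 7/9 truncated to 0.77 before averaging; 5/8 = 0.625 kept exact
        assert R_paper == pytest.approx(0.879)
        _, R_exact, _ = evaluate.precision_recall(cm)
        assert R_exact == pytest.approx((1 + 1 + 7 / 9 + 5 / 8 + 1) / 5)

    def test_identity_matrix_gives_perfect_scores(self):
        cm = ConfusionMatrix(np.eye(4, dtype=int) * 3, list("abcd"))
        P, R, per = evaluate.precision_recall(cm)
        assert P == R == 1.0
        assert all(v["precision"] == v["recall"] == 1.0 for v in per.values())

    def test_transpose_swaps_precision_and_recall(self):
        cm = mixture_series_confusion()
        P, R, _ = evaluate.precision_recall(cm)
        Pt, Rt, _ = evaluate.precision_recall(cm.transpose())
        assert Pt == pytest.approx(R)
        assert Rt == pytest.approx(P)

    def test_scores_bounded_and_perfect_iff_diagonal(self):
        cm = mixture_series_confusion()
        P, R, _ = evaluate.precision_recall(cm)
        assert 0.0 <= P <= 1.0 and 0.0 <= R <= 1.0
        assert not (P == 1.0 and R == 1.0)  # off-diagonal entries exist

    def test_never_predicted_class_warns_precision_zero(self):
        cm = ConfusionMatrix(np.array([[2, 1], [0, 0]]), ["a", "b"])
        with pytest.warns(UserWarning, match="never predicted"):
            P, _, per = evaluate.precision_recall(cm)
        assert per["b"]["precision"] == 0.0

    def test_empty_known_class_raises_undefined_recall(self):
        cm = ConfusionMatrix(np.array([[2, 0], [1, 0]]), ["a", "b"])
        with pytest.raises(EvaluationError, match="'b'"):
            evaluate.precision_recall(cm)

    def test_truncation_applies_only_to_nonterminating_ratios(self):
        # 1/3 -> 0.33 truncated; 1/4 = 0.25 exact
        cm = ConfusionMatrix(
            np.array([[1, 0], [2, 1]]), ["a", "b"]
        )
        _, _, per = evaluate.precision_recall(cm, rounding_mode="paper")
        assert per["b"]["precision"] == pytest.approx(0.33)
        _, R, per = evaluate.precision_recall(
            ConfusionMatrix(np.array([[1, 3], [0, 1]]), ["a", "b"]),
            rounding_mode="paper",
        )
        assert per["a"]["precision"] == pytest.approx(0.25)


class TestSummarize:
    def test_mixture_series_report(self):
        report = evaluate.summarize(mixture_series_confusion())
        assert report["misclassified"] == 5
        assert report["total"] == 41
        assert report["macro_precision"] == pytest.approx(0.9)
        assert report["per_class"]["B50E50"] == pytest.approx(
            {"tp": 7, "fp": 3, "fn": 2, "precision": 0.7, "recall": 7 / 9}
        )

    def test_background_series_is_perfect(self):
        report = evaluate.summarize(background_series_confusion())
        assert report["misclassified"] == 0
        assert report["macro_precision"] == report["macro_recall"] == 1.0


class TestStratifiedFolds:
    def test_folds_partition_indices(self):
        labels = ["a"] * 8 + ["b"] * 9 + ["c"] * 8
        folds = evaluate.stratified_folds(labels, k=10, seed=0)
        flat = np.concatenate(folds)
        assert sorted(flat) == list(range(25))

    def test_every_training_split_keeps_all_classes(self):
        labels = ["a"] * 8 + ["b"] * 8 + ["c"] * 9 + ["d"] * 8 + ["e"] * 8
        folds = evaluate.stratified_folds(labels, k=10, seed=3)
        labels = np.array(labels)
        for i, f in enumerate(folds):
            train = np.concatenate([g for j, g in enumerate(folds) if j != i])
            assert set(labels[train]) == set("abcde")

    def test_k_larger_than_m_rejected(self):
        with pytest.raises(EvaluationError):
            evaluate.stratified_folds(["a", "b"], k=3)


class TestKfoldEvaluate:
    def test_separated_synthetic_classes_give_diagonal_confusion(self):
        g = np.random.default_rng(0)
        centers = 50.0 * g.normal(size=(5, 12))
        raw = np.vstack([c + g.normal(size=(8, 12)) for c in centers])
        labels = [lab for lab in "abcde" for _ in range(8)]
        cm = evaluate.kfold_evaluate(raw, labels, k=10, seed=0, p=8)
        assert np.all(cm.counts == np.diag([8] * 5))

    def test_leave_one_out_bookkeeping(self):
        g = np.random.default_rng(1)
        raw = np.vstack([g.normal(size=(3, 5)), 10 + g.normal(size=(3, 5))])
        labels = ["a"] * 3 + ["b"] * 3
        cm = evaluate.kfold_evaluate(raw, labels, k=6, seed=0, p=3)
        assert cm.total == 6

    def test_fixed_seed_is_reproducible(self, small_dataset):
        _, labels, raw = small_dataset
        a = evaluate.kfold_evaluate(raw, labels, k=5, seed=42)
        b = evaluate.kfold_evaluate(raw, labels, k=5, seed=42)
        assert np.array_equal(a.counts, b.counts)
        assert a.class_order == b.class_order

    def test_row_shuffling_preserves_aggregate_counts(self, small_dataset):
        _, labels, raw = small_dataset
        g = np.random.default_rng(9)
        perm = g.permutation(len(labels))
        a = evaluate.kfold_evaluate(raw, labels, k=5, seed=1)
        b = evaluate.kfold_evaluate(
            raw[perm], [labels[i] for i in perm], k=5, seed=1
        )
        assert a.total == b.total
        assert np.array_equal(
            np.sort(a.counts.sum(axis=0)), np.sort(b.counts.sum(axis=0))
        )
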