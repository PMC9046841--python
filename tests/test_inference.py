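"""Gallery matching, confusion statistics, ROC/AUC, end-to-end evaluation."""

import numpy as np
import pytest

from dgcn import (
    ConfusionCounts,
    GallerySet,
    accuracy,
    confusion_counts,
    embed_gallery,
    predict_label,
    referable_binarize,
    referable_scores,
    roc_auc,
    sensitivity,
    specificity,
)
from dgcn.exceptions import (
    InsufficientDataError,
    InvalidInputError,
    UndefinedStatisticError,
)
from dgcn.inference import evaluate_dataset, wilson_interval


def _gallery(embeddings, labels):
    return GallerySet(
        embeddings=np.asarray(embeddings, dtype=float),
        labels=np.asarray(labels),
        classes=np.unique(labels),
    )


class TestPredictLabel:
    def test_exact_match_distance_zero(self):
        g = _gallery([[0.0, 0.0], [5.0, 5.0]], ["a", "b"])
        label, dist, idx = predict_label([5.0, 5.0], g)
        assert (label, dist, idx) == ("b", 0.0, 1)

    def test_one_dimensional_example(self):
        g = _gallery([[0.0], [10.0]], ["a", "b"])
        label, dist, _ = predict_label([2.0], g)
        assert label == "a" and dist == pytest.approx(2.0)

    def test_tie_breaks_to_lowest_index(self):
        g = _gallery([[1.0], [-1.0]], ["a", "b"])
        label, _, idx = predict_label([0.0], g)
        assert label == "a" and idx == 0

    def test_matches_exhaustive_scan_oracle(self, rng):
        g = _gallery(rng.normal(size=(20, 4)), rng.integers(0, 5, size=20))
        for _ in range(50):
            q = rng.normal(size=4)
            label, dist, idx = predict_label(q, g)
            best, bestd = None, np.inf
            for i, row in enumerate(g.embeddings):  # independent brute scan
                d = float(np.sqrt(((row - q) ** 2).sum()))
                if d < bestd:
                    best, bestd = i, d
            assert idx == best and dist == pytest.approx(bestd)

    def test_dimension_mismatch(self):
        with pytest.raises(InvalidInputError):
            predict_label([0.0], _gallery([[0.0, 1.0]], ["a"]))


class TestConfusionStatistics:
    def test_hand_values(self):
        assert sensitivity(ConfusionCounts(TP=9, FN=1, TN=0, FP=0)) == pytest.approx(0.9)
        assert specificity(ConfusionCounts(TP=0, FN=0, TN=0, FP=5)) == 0.0
        assert accuracy(ConfusionCounts(TP=3, FN=1, TN=5, FP=1)) == pytest.approx(0.8)

    def test_zero_denominators_raise(self):
        with pytest.raises(UndefinedStatisticError):
            sensitivity(ConfusionCounts(TP=0, FN=0, TN=3, FP=2))
        with pytest.raises(UndefinedStatisticError):
            specificity(ConfusionCounts(TP=1, FN=1, TN=0, FP=0))

    def test_matches_recount_oracle(self, rng):
        pred = rng.integers(0, 2, size=200).astype(bool)
        truth = rng.integers(0, 2, size=200).astype(bool)
        c = confusion_counts(pred, truth)
        # independent recount by explicit iteration
        tp = sum(1 for p, t in zip(pred, truth) if p and t)
        fn = sum(1 for p, t in zip(pred, truth) if not p and t)
        tn = sum(1 for p, t in zip(pred, truth) if not p and not t)
        fp = sum(1 for p, t in zip(pred, truth) if p and not t)
        assert (c.TP, c.FN, c.TN, c.FP) == (tp, fn, tn, fp)
        assert c.total == 200
        assert sensitivity(c) == pytest.approx(tp / (tp + fn))
        assert specificity(c) == pytest.approx(tn / (tn + fp))
        assert accuracy(c) == pytest.approx((tp + tn) / 200)


class TestReferableBinarize:
    def test_definition(self):
        assert list(referable_binarize([0, 1, 2, 3, 4])) == [0, 0, 1, 1, 1]

    def test_out_of_range_rejected(self):
        with pytest.raises(InvalidInputError):
            referable_binarize([0, 5])


class TestRocAuc:
    def test_perfect_separation(self):
        roc = roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert roc.auc == pytest.approx(1.0)

    def test_constant_scores_chance(self):
        roc = roc_auc([0.5] * 10, [1, 0] * 5)
        assert roc.auc == pytest.approx(0.5)

    def test_hand_value(self):
        roc = roc_auc([0.9, 0.8, 0.3, 0.1], [1, 0, 1, 0])
        assert roc.auc == pytest.approx(0.75)

    def test_rates_monotone(self, rng):
        roc = roc_auc(rng.normal(size=40), rng.integers(0, 2, size=40))
        assert np.all(np.diff(roc.tpr) >= 0) and np.all(np.diff(roc.fpr) >= 0)

    def test_single_class_truth_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            roc_auc([0.1, 0.2], [1, 1])

    def test_matches_pair_counting_oracle(self, rng):
        for _ in range(30):
            n = int(rng.integers(4, 30))
            scores = np.round(rng.normal(size=n), 1)  # induce ties
            truth = rng.integers(0, 2, size=n)
            if truth.min() == truth.max():
                continue
            auc = roc_auc(scores, truth).auc
            pos, neg = scores[truth == 1], scores[truth == 0]
            conc = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
            assert auc == pytest.approx(conc / (len(pos) * len(neg)), abs=1e-10)

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        scores = rng.normal(size=60)
        truth = rng.integers(0, 2, size=60)
        assert roc_auc(scores, truth).auc == pytest.approx(
            roc_auc_score(truth, scores), abs=1e-12
        )


class TestWilsonInterval:
    def test_bounds_and_coverage_shape(self):
        lo, hi = wilson_interval(90, 100)
        assert 0 <= lo < 0.9 < hi <= 1


class TestGalleryEmbedding:
    def test_shapes_classes_and_determinism(self, tiny_set, small_state):
        imgs, grades = tiny_set.images[:9], tiny_set.grades[:9]
        g1 = embed_gallery(imgs, grades, small_state)
        g2 = embed_gallery(imgs, grades, small_state)
        assert g1.embeddings.shape == (9, 8)
        assert set(g1.classes) == set(np.unique(grades))
        assert np.array_equal(g1.embeddings, g2.embeddings)
        assert np.array_equal(g1.labels, grades)

    def test_referable_scores_need_both_sides(self, rng):
        g = _gallery(rng.normal(size=(4, 2)), [3, 4, 3, 4])
        with pytest.raises(UndefinedStatisticError):
            referable_scores(rng.normal(size=(2, 2)), g)


class TestEvaluateDataset:
    def test_self_retrieval_is_perfect(self, tiny_set, small_state):
        imgs = tiny_set.images[:12]
        grades = tiny_set.grades[:12]
        gallery = embed_gallery(imgs, grades, small_state)
        # each query is matched in its own {query} + gallery graph, so a
        # query identical to a gallery image sits at distance exactly zero
        rep = evaluate_dataset(imgs, grades, gallery, small_state)
        assert rep["n_queries"] == 12
        assert np.sum(rep["confusion_matrix"]) == 12
        assert rep["multiclass_accuracy"] == 1.0
        assert max(rep["match_distances"]) == 0.0

    def test_metrics_invariant_under_query_shuffle(self, tiny_set, small_state, rng):
        gal_imgs, gal_grades = tiny_set.images[:9], tiny_set.grades[:9]
        q_imgs, q_grades = tiny_set.images[9:21], tiny_set.grades[9:21]
        gallery = embed_gallery(gal_imgs, gal_grades, small_state)
        rep1 = evaluate_dataset(q_imgs, q_grades, gallery, small_state)
        perm = rng.permutation(len(q_imgs))
        rep2 = evaluate_dataset(
            [q_imgs[i] for i in perm], np.asarray(q_grades)[perm], gallery, small_state
        )
        for key in ("multiclass_accuracy", "accuracy", "sensitivity", "specificity", "auc"):
            if key in rep1:
                assert rep1[key] == pytest.approx(rep2[key], abs=1e-12)
        assert np.sum(rep1["confusion_matrix"]) == np.sum(rep2["confusion_matrix"])

    def test_all_correct_predictions_give_unit_rates(self):
        c = confusion_counts([1, 1, 0, 0], [1, 1, 0, 0])
        assert sensitivity(c) == 1.0 and specificity(c) == 1.0 and accuracy(c) == 1.0

    def test_empty_query_rejected(self, tiny_set, small_state):
        gallery = embed_gallery(tiny_set.images[:9], tiny_set.grades[:9], small_state)
        with pytest.raises(InsufficientDataError):
            evaluate_dataset([], [], gallery, small_state)

    def test_embeddings_tsv_written(self, tiny_set, small_state, tmp_path):
        gallery = embed_gallery(tiny_set.images[:9], tiny_set.grades[:9], small_state)
        out = tmp_path / "emb.tsv"
        evaluate_dataset(
            tiny_set.images[9:15], tiny_set.grades[9:15], gallery, small_state,
            out_embeddings_path=out,
        )
        lines = out.read_text().strip().split("\n")
        assert len(lines) == 7  # header + 6 queries
        assert lines[0].endswith("true_grade\tpredicted_grade")
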