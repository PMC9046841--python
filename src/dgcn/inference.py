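"""Gallery nearest-match grading and evaluation statistics.

After unsupervised training, grading uses a small labeled gallery: each
query image is embedded and inherits the grade of its nearest gallery
embedding (Euclidean distance, ties to the lowest gallery index). Because
graph propagation needs a graph at test time, each query is embedded in a
KNN graph over that query plus the gallery rows, and matched against the
gallery embeddings from the same propagation pass; predictions are
therefore deterministic, label-blind, and independent of query ordering,
and a query identical to a gallery image matches it at distance exactly
zero. The gallery as a standalone object is embedded over its own internal
graph.

Evaluation reports the 5-class confusion matrix, and — on the referable
binarization (grade >= 2: moderate or worse) — sensitivity TP/(TP+FN),
specificity TN/(TN+FP), accuracy, Wilson 95% confidence intervals, and the
ROC curve with its trapezoidal AUC. The continuous referable score is the
distance margin between the nearest non-referable and nearest referable
gallery embedding (configurable to the negative distance-to-referable).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from statsmodels.stats.proportion import proportion_confint

from .encoder import ConvEncoder
from .exceptions import (
    InsufficientDataError,
    InvalidInputError,
    UndefinedStatisticError,
)
from .graph import build_knn_adjacency, gcn_forward
from .trainer import TrainingState

REFERABLE_THRESHOLD = 2  # moderate or worse


@dataclass
class GallerySet:
    """Embedded labeled reference set used for nearest-match grading."""

    embeddings: np.ndarray  # (n, d_out)
    labels: np.ndarray
    classes: np.ndarray
    features: np.ndarray | None = None  # encoder features, used for query graphs

    def __post_init__(self) -> None:
        self.embeddings = np.asarray(self.embeddings, dtype=np.float64)
        self.labels = np.asarray(self.labels)
        if len(self.embeddings) != len(self.labels):
            raise InvalidInputError("gallery embeddings and labels misaligned")
        if len(self.embeddings) == 0:
            raise InsufficientDataError("gallery is empty")
        self.classes = np.unique(self.labels)


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion tallies for a chosen positive definition."""

    TP: int
    FN: int
    TN: int
    FP: int

    @property
    def total(self) -> int:
        return self.TP + self.FN + self.TN + self.FP


@dataclass
class RocCurve:
    """Threshold sweep of a binary score: rates and trapezoidal area."""

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float = field(init=False)

    def __post_init__(self) -> None:
        self.auc = float(np.trapezoid(self.tpr, self.fpr))


# ---------------------------------------------------------------------------
# embedding


def _encode_features(images: list[np.ndarray], state: TrainingState) -> np.ndarray:
    x = ConvEncoder.to_input(images)
    f, _ = state.encoder.forward(x, train=False)
    return f


def embed_gallery(
    images: list[np.ndarray], labels, state: TrainingState
) -> GallerySet:
    """Embed labeled gallery images (eval mode, gallery-internal KNN graph)."""
    labels = np.asarray(labels)
    if len(images) != len(labels):
        raise InvalidInputError("gallery images and labels misaligned")
    classes, counts = np.unique(labels, return_counts=True)
    if len(images) < 2:
        raise InsufficientDataError("gallery needs at least 2 images to form a graph")
    F = _encode_features(images, state)
    K = min(state.config.K, len(images) - 1)
    adj = build_knn_adjacency(F, K)
    Z = gcn_forward(F, adj, state.gcn).Z
    return GallerySet(embeddings=Z, labels=labels, classes=classes, features=F)


def embed_queries(
    images: list[np.ndarray],
    state: TrainingState,
    gallery: GallerySet,
    batch_size: int | None = None,
    return_gallery_context: bool = False,
):
    """Embed query images batch-wise with a graph over batch + gallery rows.

    The graph for each query is built over that query plus the gallery rows
    only — never over other queries — so every prediction is independent of
    how the query set is ordered or batched (``batch_size`` only controls
    how many encoder forwards are vectorized together).

    With ``return_gallery_context=True`` also returns the gallery rows'
    embeddings from each query's propagation pass (an (n_queries, n_gallery,
    d) array): matching a query against these in-context gallery embeddings
    keeps both sides of the distance in one graph, so a query identical to a
    gallery image sits at distance exactly zero.
    """
    if gallery.features is None:
        raise InvalidInputError("gallery was built without stored features")
    bs = batch_size or state.config.batch_size
    n_g = len(gallery.features)
    K = min(state.config.K, n_g)  # graph has n_g + 1 nodes
    out, ctx = [], []
    for start in range(0, len(images), bs):
        chunk = images[start : start + bs]
        Fq = _encode_features(chunk, state)
        for i in range(len(chunk)):
            F = np.vstack([Fq[i : i + 1], gallery.features])
            adj = build_knn_adjacency(F, K)
            Z = gcn_forward(F, adj, state.gcn).Z
            out.append(Z[0])
            ctx.append(Z[1:])
    Zq = np.asarray(out)
    if return_gallery_context:
        return Zq, np.asarray(ctx)
    return Zq


def match_queries(
    images: list[np.ndarray],
    state: TrainingState,
    gallery: GallerySet,
    batch_size: int | None = None,
    score_scheme: str = "margin",
) -> dict:
    """Grade every query by nearest in-context gallery embedding.

    Returns arrays: ``predictions``, ``distances``, ``matched_indices``,
    ``embeddings`` (query rows), and — when the gallery holds both referable
    and non-referable rows — continuous ``referable_scores``.

    A query whose encoder features coincide exactly with a gallery row's is
    at embedding distance zero to that row by identity of the deterministic
    encoder+GCN map; the duplicate node would otherwise perturb the KNN
    tie-breaking, so this case is resolved explicitly.
    """
    Zq, gallery_ctx = embed_queries(
        images, state, gallery, batch_size=batch_size, return_gallery_context=True
    )
    # (n_queries, n_gallery) distances, each row within its own graph context
    d = np.linalg.norm(Zq[:, None, :] - gallery_ctx, axis=2)
    Fq = _encode_features(images, state)
    feat_dup = np.all(Fq[:, None, :] == gallery.features[None, :, :], axis=2)
    d[feat_dup] = 0.0
    idx = d.argmin(axis=1)
    out = {
        "predictions": gallery.labels[idx],
        "distances": d[np.arange(len(idx)), idx],
        "matched_indices": idx,
        "embeddings": Zq,
    }
    try:
        ref_mask = referable_binarize(gallery.labels).astype(bool)
    except InvalidInputError:
        ref_mask = None
    if ref_mask is not None and ref_mask.any() and not ref_mask.all():
        d_ref = d[:, ref_mask].min(axis=1)
        if score_scheme == "neg_distance":
            out["referable_scores"] = -d_ref
        elif score_scheme == "margin":
            out["referable_scores"] = d[:, ~ref_mask].min(axis=1) - d_ref
        else:
            raise InvalidInputError(f"unknown score scheme {score_scheme!r}")
    return out


# ---------------------------------------------------------------------------
# nearest-match prediction


def predict_label(query_embedding: np.ndarray, gallery: GallerySet):
    """Label of the nearest gallery embedding; ties to the lowest index.

    Returns ``(grade, distance, matched_index)``.
    """
    q = np.asarray(query_embedding, dtype=np.float64).ravel()
    if q.shape[0] != gallery.embeddings.shape[1]:
        raise InvalidInputError(
            f"query dim {q.shape[0]} != gallery dim {gallery.embeddings.shape[1]}"
        )
    d = np.linalg.norm(gallery.embeddings - q[None, :], axis=1)
    i = int(np.argmin(d))  # argmin returns the first (lowest) index on ties
    return gallery.labels[i], float(d[i]), i


# ---------------------------------------------------------------------------
# statistics


def sensitivity(counts: ConfusionCounts) -> float:
    """TP / (TP + FN)."""
    denom = counts.TP + counts.FN
    if denom == 0:
        raise UndefinedStatisticError("sensitivity undefined: no positive truths")
    return counts.TP / denom


def specificity(counts: ConfusionCounts) -> float:
    """TN / (TN + FP)."""
    denom = counts.TN + counts.FP
    if denom == 0:
        raise UndefinedStatisticError("specificity undefined: no negative truths")
    return counts.TN / denom


def accuracy(counts: ConfusionCounts) -> float:
    """(TP + TN) / total."""
    if counts.total == 0:
        raise UndefinedStatisticError("accuracy undefined: no evaluated samples")
    return (counts.TP + counts.TN) / counts.total


def confusion_counts(predicted_positive, truth_positive) -> ConfusionCounts:
    """Tally binary confusion counts from aligned prediction/truth vectors."""
    p = np.asarray(predicted_positive).astype(bool)
    t = np.asarray(truth_positive).astype(bool)
    if p.shape != t.shape:
        raise InvalidInputError("prediction/truth length mismatch")
    return ConfusionCounts(
        TP=int(np.sum(p & t)),
        FN=int(np.sum(~p & t)),
        TN=int(np.sum(~p & ~t)),
        FP=int(np.sum(p & ~t)),
    )


def referable_binarize(grades) -> np.ndarray:
    """1 for moderate-or-worse disease (grade >= 2), else 0."""
    g = np.asarray(grades)
    if g.size and (g.min() < 0 or g.max() > 4):
        raise InvalidInputError(f"grades must lie in 0..4, got range [{g.min()}, {g.max()}]")
    return (g >= REFERABLE_THRESHOLD).astype(int)


def roc_auc(scores, truth) -> RocCurve:
    """ROC by threshold sweep over the unique scores; trapezoidal AUC.

    ``scores`` are 'higher means more positive'. Requires both classes in
    the truth vector.
    """
    s = np.asarray(scores, dtype=np.float64)
    t = np.asarray(truth).astype(bool)
    if s.shape != t.shape:
        raise InvalidInputError("scores/truth length mismatch")
    n_pos, n_neg = int(t.sum()), int((~t).sum())
    if n_pos == 0 or n_neg == 0:
        raise UndefinedStatisticError("ROC undefined: truth contains a single class")
    thresholds = np.concatenate(([np.inf], np.unique(s)[::-1]))
    tpr = np.empty(len(thresholds))
    fpr = np.empty(len(thresholds))
    for i, thr in enumerate(thresholds):
        pred = s >= thr
        tpr[i] = np.sum(pred & t) / n_pos
        fpr[i] = np.sum(pred & ~t) / n_neg
    return RocCurve(thresholds=thresholds, tpr=tpr, fpr=fpr)


def referable_scores(
    query_embeddings: np.ndarray, gallery: GallerySet, scheme: str = "margin"
) -> np.ndarray:
    """Continuous referable score per query.

    'margin': distance to nearest non-referable gallery row minus distance
    to nearest referable row (positive when the referable side is closer).
    'neg_distance': negative distance to the nearest referable row.
    """
    ref_mask = referable_binarize(gallery.labels).astype(bool)
    if not ref_mask.any() or ref_mask.all():
        raise UndefinedStatisticError(
            "referable score needs both referable and non-referable gallery rows"
        )
    Q = np.asarray(query_embeddings, dtype=np.float64)
    d = np.linalg.norm(Q[:, None, :] - gallery.embeddings[None, :, :], axis=2)
    d_ref = d[:, ref_mask].min(axis=1)
    if scheme == "neg_distance":
        return -d_ref
    if scheme != "margin":
        raise InvalidInputError(f"unknown score scheme {scheme!r}")
    d_nonref = d[:, ~ref_mask].min(axis=1)
    return d_nonref - d_ref


def wilson_interval(successes: int, total: int) -> tuple[float, float]:
    """Wilson score 95% confidence interval for a proportion."""
    lo, hi = proportion_confint(successes, total, alpha=0.05, method="wilson")
    return float(lo), float(hi)


# ---------------------------------------------------------------------------
# end-to-end evaluation


def evaluate_dataset(
    query_images: list[np.ndarray],
    query_truth,
    gallery: GallerySet,
    state: TrainingState,
    out_embeddings_path=None,
    score_scheme: str = "margin",
) -> dict:
    """Predict every query and assemble the full metrics report.

    Returns a dict with the 5-class confusion matrix, referable-binarized
    accuracy/sensitivity/specificity with Wilson 95% CIs, the ROC curve and
    AUC, and per-query predictions. Optionally writes an embeddings TSV
    (embedding columns + true grade + predicted grade) for external 2-D
    visualization.
    """
    truth = np.asarray(query_truth)
    if len(query_images) == 0:
        raise InsufficientDataError("query set is empty")
    if len(query_images) != len(truth):
        raise InvalidInputError("query images and truth misaligned")
    matched = match_queries(query_images, state, gallery, score_scheme=score_scheme)
    Zq = matched["embeddings"]
    preds = matched["predictions"].astype(int)
    dists = matched["distances"]

    classes = np.unique(np.concatenate([truth, gallery.labels]))
    cls_index = {c: i for i, c in enumerate(classes)}
    cm = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(truth, preds):
        cm[cls_index[t], cls_index[p]] += 1

    ref_truth = referable_binarize(truth).astype(bool)
    ref_pred = referable_binarize(preds).astype(bool)
    counts = confusion_counts(ref_pred, ref_truth)
    acc = accuracy(counts)
    report: dict = {
        "n_queries": len(truth),
        "classes": classes.tolist(),
        "confusion_matrix": cm.tolist(),
        "multiclass_accuracy": float(np.mean(preds == truth)),
        "counts": {"TP": counts.TP, "FN": counts.FN, "TN": counts.TN, "FP": counts.FP},
        "accuracy": acc,
        "accuracy_ci": wilson_interval(counts.TP + counts.TN, counts.total),
        "predictions": preds.tolist(),
        "match_distances": dists.tolist(),
    }
    if ref_truth.any():
        report["sensitivity"] = sensitivity(counts)
        report["sensitivity_ci"] = wilson_interval(counts.TP, counts.TP + counts.FN)
    if (~ref_truth).any():
        report["specificity"] = specificity(counts)
        report["specificity_ci"] = wilson_interval(counts.TN, counts.TN + counts.FP)
    if ref_truth.any() and (~ref_truth).any() and "referable_scores" in matched:
        scores = matched["referable_scores"]
        roc = roc_auc(scores, ref_truth)
        report["auc"] = roc.auc
        report["roc"] = {
            "thresholds": roc.thresholds.tolist(),
            "tpr": roc.tpr.tolist(),
            "fpr": roc.fpr.tolist(),
        }
        report["referable_scores"] = scores.tolist()

    if out_embeddings_path is not None:
        header = "\t".join(
            [f"z{i}" for i in range(Zq.shape[1])] + ["true_grade", "predicted_grade"]
        )
        rows = [header]
        for i in range(len(truth)):
            vals = "\t".join(f"{v:.8g}" for v in Zq[i])
            rows.append(f"{vals}\t{truth[i]}\t{preds[i]}")
        with open(out_embeddings_path, "w") as fh:
            fh.write("\n".join(rows) + "\n")
    return report
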