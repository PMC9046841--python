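"""Model/Results front end.

``DGCNModel`` holds the unlabeled training images and the run
configuration; ``fit()`` runs the unsupervised optimization and returns a
``DGCNResults`` carrying the trained state, the loss trajectory, and the
downstream operations (embedding, gallery grading, evaluation, plots).
The underlying modules (:mod:`~dgcn.trainer`, :mod:`~dgcn.inference`, ...)
remain usable directly.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from . import _io, inference, trainer
from .exceptions import InvalidInputError
from .trainer import TrainConfig, TrainingState


class DGCNModel:
    """Deep graph correlation network over an unlabeled image collection.

    Parameters
    ----------
    images : list of (H, W, 3) float RGB arrays in [0, 1]. Ground-truth
        grades are deliberately not accepted: training is label-free.
    config : TrainConfig, optional; defaults are CPU-scale.
    """

    def __init__(self, images: list[np.ndarray], config: TrainConfig | None = None):
        if not images:
            raise InvalidInputError("no training images given")
        self.images = images
        self.config = config or TrainConfig()

    @classmethod
    def from_directory(cls, data_dir, config: TrainConfig | None = None) -> "DGCNModel":
        """Build from a directory of PNG/JPEG files (any manifest is ignored:
        training never reads labels)."""
        images, _ = _io.load_image_dir(Path(data_dir))
        return cls(images, config)

    def fit(self, out_dir=None, progress: bool = False) -> "DGCNResults":
        state = trainer.fit(self.images, self.config, out_dir=out_dir, progress=progress)
        return DGCNResults(self, state)


class DGCNResults:
    """Trained embedding with gallery-based grading attached."""

    def __init__(self, model: DGCNModel | None, state: TrainingState):
        self.model = model
        self.state = state
        self.config = state.config

    # -- persistence ---------------------------------------------------------
    def save(self, path) -> None:
        self.state.save(path)

    @classmethod
    def from_checkpoint(cls, path) -> "DGCNResults":
        return cls(None, TrainingState.load(path))

    # -- downstream operations ----------------------------------------------
    def build_gallery(self, images, labels) -> inference.GallerySet:
        return inference.embed_gallery(images, labels, self.state)

    def predict(self, query_images, gallery: inference.GallerySet):
        """Nearest-gallery grades for query images.

        Returns ``(grades, distances, matched_indices)`` arrays.
        """
        m = inference.match_queries(query_images, self.state, gallery)
        return m["predictions"], m["distances"], m["matched_indices"]

    def evaluate(self, query_images, query_truth, gallery: inference.GallerySet,
                 out_embeddings_path=None) -> dict:
        return inference.evaluate_dataset(
            query_images, query_truth, gallery, self.state,
            out_embeddings_path=out_embeddings_path,
        )

    @property
    def loss_history(self):
        return self.state.loss_history

    # -- presentation ---------------------------------------------------------
    def summary(self, evaluation: dict | None = None) -> str:
        """Plain-text run summary; pass an evaluation report to append the
        grading metrics table."""
        cfg = self.config
        lines = [
            "Deep Graph Correlation Network — run summary",
            "=" * 52,
            f"encoder            {cfg.encoder.architecture} (d={cfg.encoder.feature_dim})",
            f"gcn layers         {cfg.gcn.n_layers} (self-loops={cfg.gcn.add_self_loops})",
            f"batch / K / lambda {cfg.batch_size} / {cfg.K} / {cfg.resolved_lam}",
            f"alpha / beta / m   {cfg.weights.alpha} / {cfg.weights.beta} / {cfg.weights.margin}",
            f"optimizer          {cfg.optimizer_name} lr={cfg.learning_rate} "
            f"momentum={cfg.momentum}",
            f"epochs / steps     {self.state.epoch} / {self.state.step}",
        ]
        if self.loss_history:
            first, last = self.loss_history[0], self.loss_history[-1]
            lines += [
                f"total loss         {first.total:.4f} -> {last.total:.4f}",
                f"  pc               {first.pc:.4f} -> {last.pc:.4f}",
                f"  gc               {first.gc:.4f} -> {last.gc:.4f}",
                f"  ti               {first.ti:.4f} -> {last.ti:.4f}",
            ]
        if evaluation is not None:
            lines += ["-" * 52, f"queries            {evaluation['n_queries']}"]
            lines.append(f"5-class accuracy   {evaluation['multiclass_accuracy']:.3f}")

            def _ci(key):
                lo, hi = evaluation[f"{key}_ci"]
                return f"{evaluation[key] * 100:.1f}% (95% CI {lo * 100:.1f}–{hi * 100:.1f})"

            lines.append(f"referable accuracy {_ci('accuracy')}")
            if "sensitivity" in evaluation:
                lines.append(f"sensitivity        {_ci('sensitivity')}")
            if "specificity" in evaluation:
                lines.append(f"specificity        {_ci('specificity')}")
            if "auc" in evaluation:
                lines.append(f"AUC                {evaluation['auc']:.3f}")
        return "\n".join(lines)

    # -- plotting -------------------------------------------------------------
    def plot_loss(self, ax=None):
        """Loss-component trajectories over training steps."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        steps = np.arange(1, len(self.loss_history) + 1)
        for name in ("total", "pc", "gc", "ti"):
            ax.plot(steps, [getattr(r, name) for r in self.loss_history], label=name)
        ax.set_xlabel("step")
        ax.set_ylabel("loss")
        ax.legend()
        return ax

    @staticmethod
    def plot_roc(evaluation: dict, ax=None):
        """ROC curve from an evaluation report."""
        import matplotlib.pyplot as plt

        if "roc" not in evaluation:
            raise InvalidInputError("evaluation report carries no ROC data")
        if ax is None:
            _, ax = plt.subplots()
        roc = evaluation["roc"]
        ax.plot(roc["fpr"], roc["tpr"])
        ax.plot([0, 1], [0, 1], linestyle=":", color="grey")
        ax.set_xlabel("false positive rate")
        ax.set_ylabel("true positive rate")
        ax.set_title(f"AUC = {evaluation['auc']:.3f}")
        return ax
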