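"""Unsupervised optimization loop.

One training step runs the full pipeline on a mini-batch: encode the
images, build the KNN graph from the features, propagate through the GCN,
estimate pairwise pseudo-labels from shared-neighbor counts, encode a
randomly transformed copy of the batch through the same graph, assemble the
combined loss, and take one SGD step on the encoder parameters theta and
the GCN weights W. Ground-truth grades never enter: ``fit`` accepts images
only, so label blindness is enforced by the interface.

Reproducibility: one global seed fans out into independent derived streams
(parameter init, epoch shuffling, transform sampling), and checkpoints
capture parameters, optimizer velocity, and all RNG states, so a resumed
run reproduces the uninterrupted trajectory bit for bit.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import _io
from ._nn import SGD, Adam
from .encoder import ConvEncoder, EncoderConfig, TransformSpec, apply_transform
from .exceptions import ConfigurationError, InsufficientDataError
from .graph import GcnConfig, GraphConvNet, build_knn_adjacency
from .objectives import (
    LossReport,
    LossWeights,
    estimate_pairwise_labels,
    graph_center_loss,
    graph_center_loss_grad,
    pseudo_contrastive_loss,
    pseudo_contrastive_loss_grad,
    total_loss,
    transform_invariant_loss,
    transform_invariant_loss_grad,
)


@dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters of the unsupervised run.

    The backbone, graph size K, loss balance (alpha, beta, margin m), the
    shared-neighbor threshold lambda (default floor(K/2)), and the
    transformation family are all explicit knobs; none of them is fixed by
    the method itself.
    """

    batch_size: int = 8
    K: int = 3
    epochs: int = 15
    learning_rate: float = 1e-3
    momentum: float = 0.9  # used by the sgd optimizer only
    optimizer_name: str = "adam"
    weights: LossWeights = field(default_factory=LossWeights)
    lam: int | None = None
    transform: TransformSpec = field(default_factory=TransformSpec)
    seed: int = 0
    gcn: GcnConfig = field(default_factory=GcnConfig)
    encoder: EncoderConfig = field(default_factory=EncoderConfig)
    rebuild_graph_for_transformed: bool = False
    ti_squared: bool = False

    def __post_init__(self) -> None:
        if self.batch_size < 4:
            raise ConfigurationError("batch_size must be >= 4")
        if not 1 <= self.K < self.batch_size:
            raise ConfigurationError("K must satisfy 1 <= K < batch_size")
        if self.optimizer_name not in ("sgd", "adam"):
            raise ConfigurationError(f"unknown optimizer {self.optimizer_name!r}")
        if self.lam is not None and not 0 <= self.lam <= self.K:
            raise ConfigurationError("lambda must lie in [0, K]")

    @property
    def resolved_lam(self) -> int:
        return self.K // 2 if self.lam is None else self.lam


class TrainingState:
    """Everything needed to continue or apply a run: parameters, optimizer
    velocity, epoch/step counters, RNG streams, loss history."""

    def __init__(self, config: TrainConfig) -> None:
        self.config = config
        root = np.random.SeedSequence(config.seed)
        init_ss, shuffle_ss, transform_ss = root.spawn(3)
        init_rng = np.random.default_rng(init_ss)
        self.encoder = ConvEncoder(config.encoder, init_rng)
        self.gcn = GraphConvNet(config.gcn, config.encoder.feature_dim, init_rng)
        if config.optimizer_name == "adam":
            self.optimizer = Adam(lr=config.learning_rate)
        else:
            self.optimizer = SGD(lr=config.learning_rate, momentum=config.momentum)
        self.shuffle_rng = np.random.default_rng(shuffle_ss)
        self.transform_rng = np.random.default_rng(transform_ss)
        self.epoch = 0
        self.step = 0
        self.loss_history: list[LossReport] = []

    # -- parameters ---------------------------------------------------------
    def named_params(self) -> dict[str, np.ndarray]:
        return {**self.encoder.named_params(), **self.gcn.named_params()}

    def named_grads(self) -> dict[str, np.ndarray]:
        return {**self.encoder.named_grads(), **self.gcn.named_grads()}

    def zero_grad(self) -> None:
        self.encoder.zero_grad()
        self.gcn.zero_grad()

    # -- persistence ---------------------------------------------------------
    def save(self, path) -> None:
        arrays = {f"param/{k}": v for k, v in self.named_params().items()}
        for k, v in self.optimizer.state_arrays().items():
            arrays[f"opt/{k}"] = v
        meta = {
            "config": _config_to_jsonable(self.config),
            "epoch": self.epoch,
            "step": self.step,
            "rng": {
                "shuffle": self.shuffle_rng.bit_generator.state,
                "transform": self.transform_rng.bit_generator.state,
            },
            "loss_history": [dataclasses.asdict(r) for r in self.loss_history],
        }
        _io.save_arrays(path, arrays, meta)

    @classmethod
    def load(cls, path) -> "TrainingState":
        arrays, meta = _io.load_arrays(path)
        config = _config_from_jsonable(meta["config"])
        state = cls(config)
        params = state.named_params()
        opt_arrays = {}
        for name, arr in arrays.items():
            kind, key = name.split("/", 1)
            if kind == "param":
                params[key][...] = arr
            elif kind == "opt":
                opt_arrays[key] = arr
        if opt_arrays:
            state.optimizer.load_state_arrays(opt_arrays)
        state.epoch = meta["epoch"]
        state.step = meta["step"]
        state.shuffle_rng.bit_generator.state = meta["rng"]["shuffle"]
        state.transform_rng.bit_generator.state = meta["rng"]["transform"]
        state.loss_history = [LossReport(**r) for r in meta["loss_history"]]
        return state


def _config_to_jsonable(config: TrainConfig) -> dict:
    d = dataclasses.asdict(config)
    return d


def _config_from_jsonable(d: dict) -> TrainConfig:
    d = dict(d)
    if isinstance(d.get("weights"), dict):
        d["weights"] = LossWeights(**d["weights"])
    if isinstance(d.get("transform"), dict):
        tf = dict(d["transform"])
        if "rotation_range" in tf:
            tf["rotation_range"] = tuple(tf["rotation_range"])
        d["transform"] = TransformSpec(**tf)
    if isinstance(d.get("gcn"), dict):
        gc = dict(d["gcn"])
        if gc.get("layer_dims") is not None:
            gc["layer_dims"] = tuple(gc["layer_dims"])
        d["gcn"] = GcnConfig(**gc)
    if isinstance(d.get("encoder"), dict):
        enc = dict(d["encoder"])
        if enc.get("channels") is not None:
            enc["channels"] = tuple(enc["channels"])
        d["encoder"] = EncoderConfig(**enc)
    return TrainConfig(**d)


# ---------------------------------------------------------------------------


def compute_step_loss(
    state: TrainingState,
    x: np.ndarray,
    x_t: np.ndarray,
    *,
    with_grad: bool = True,
    frozen_structure: tuple | None = None,
) -> LossReport:
    """Forward (and optionally backward) pass of the combined objective.

    ``frozen_structure`` = (A, neighbor_sets, labels) pins the discrete
    graph/labels — used by the finite-difference gradient check, which must
    differentiate the loss at fixed structure exactly as the backward pass
    treats it.
    """
    cfg = state.config
    F, cacheF = state.encoder.forward(x)
    if frozen_structure is None:
        adj = build_knn_adjacency(F, cfg.K)
        labels = estimate_pairwise_labels(adj.neighbor_sets, cfg.resolved_lam)
        A = adj.A
    else:
        A, _, labels = frozen_structure
    A_hat = state.gcn.prepare_adjacency(A)
    Z, cacheZ = state.gcn.forward(F, A_hat)

    F_t, cacheFt = state.encoder.forward(x_t)
    if cfg.rebuild_graph_for_transformed and frozen_structure is None:
        A_hat_t = state.gcn.prepare_adjacency(build_knn_adjacency(F_t, cfg.K).A)
    else:
        A_hat_t = A_hat  # shared graph keeps Z and Z' row-comparable
    Z_t, cacheZt = state.gcn.forward(F_t, A_hat_t)

    w = cfg.weights
    pc = pseudo_contrastive_loss(Z, labels, w.margin)
    gc = graph_center_loss(Z, A)
    ti = transform_invariant_loss(Z, Z_t, squared=cfg.ti_squared)
    report = total_loss(pc, gc, ti, w)

    if with_grad:
        dZ = pseudo_contrastive_loss_grad(Z, labels, w.margin)
        dZ += w.alpha * graph_center_loss_grad(Z, A)
        g_ti, g_ti_t = transform_invariant_loss_grad(Z, Z_t, squared=cfg.ti_squared)
        dZ += w.beta * g_ti
        dZ_t = w.beta * g_ti_t
        state.zero_grad()
        dF = state.gcn.backward(dZ, cacheZ)
        dF_t = state.gcn.backward(dZ_t, cacheZt)
        state.encoder.backward(dF, cacheF)
        state.encoder.backward(dF_t, cacheFt)
    return report


def train_step(
    batch: list[np.ndarray], state: TrainingState, config: TrainConfig | None = None
) -> tuple[TrainingState, LossReport]:
    """One optimization step on a mini-batch; returns the pre-update loss."""
    cfg = config or state.config
    if len(batch) != cfg.batch_size:
        raise ConfigurationError(
            f"batch has {len(batch)} images; config.batch_size is {cfg.batch_size}"
        )
    x = ConvEncoder.to_input(batch)
    transformed = [
        apply_transform(im, cfg.transform, state.transform_rng) for im in batch
    ]
    x_t = ConvEncoder.to_input(transformed)
    report = compute_step_loss(state, x, x_t, with_grad=True)
    state.optimizer.step(state.named_params(), state.named_grads())
    state.step += 1
    state.loss_history.append(report)
    return state, report


def fit(
    images: list[np.ndarray],
    config: TrainConfig,
    out_dir=None,
    state: TrainingState | None = None,
    progress: bool = False,
) -> TrainingState:
    """Run ``config.epochs`` epochs of shuffled mini-batch steps.

    The final partial batch of each epoch is dropped (the KNN graph and the
    pairwise normalizers assume a fixed batch size). With ``out_dir`` set,
    writes ``checkpoint.bin``, ``loss_trace.tsv`` (step, pc, gc, ti, total)
    and ``config_resolved.json``.
    """
    n = len(images)
    if n < config.batch_size:
        raise InsufficientDataError(
            f"dataset has {n} images; at least one batch of {config.batch_size} required"
        )
    if state is None:
        state = TrainingState(config)
    n_batches = n // config.batch_size
    while state.epoch < config.epochs:
        order = state.shuffle_rng.permutation(n)
        for b in range(n_batches):
            idx = order[b * config.batch_size : (b + 1) * config.batch_size]
            batch = [images[i] for i in idx]
            _, report = train_step(batch, state, config)
            if progress:
                print(
                    f"epoch {state.epoch + 1}/{config.epochs} step {state.step}: "
                    f"total={report.total:.4f} pc={report.pc:.4f} "
                    f"gc={report.gc:.4f} ti={report.ti:.4f}"
                )
        state.epoch += 1
        if out_dir is not None:
            _write_run_outputs(state, out_dir)
    if out_dir is not None:
        _write_run_outputs(state, out_dir)
    return state


def _write_run_outputs(state: TrainingState, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    state.save(out / "checkpoint.bin")
    lines = ["step\tpc\tgc\tti\ttotal"]
    for i, r in enumerate(state.loss_history, start=1):
        lines.append(f"{i}\t{r.pc:.12g}\t{r.gc:.12g}\t{r.ti:.12g}\t{r.total:.12g}")
    (out / "loss_trace.tsv").write_text("\n".join(lines) + "\n")
    (out / "config_resolved.json").write_text(
        json.dumps(_config_to_jsonable(state.config), indent=2, sort_keys=True) + "\n"
    )
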