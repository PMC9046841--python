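"""Per-batch KNN graph construction and graph-convolutional propagation.

Each mini-batch of CNN features F_b is turned into a K-nearest-neighbor
graph (Euclidean metric, ties broken by lowest index, directed edges
symmetrized by logical OR) and propagated through graph convolution layers

    X^(l) = sigma( D^{-1/2} A D^{-1/2} X^(l-1) W^(l) ),   X^(0) = F_b,

with A augmented by self-loops before normalization (configurable) and the
last layer left linear so the embedding geometry is not clamped to the
non-negative orthant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._nn import DTYPE, _he_init
from .encoder import FeatureBatch
from .exceptions import (
    ConfigurationError,
    DegenerateGraphError,
    InvalidInputError,
)


@dataclass
class AdjacencyMatrix:
    """Symmetrized binary KNN connectivity for one mini-batch.

    ``A`` has zero diagonal; ``neighbor_sets[k]`` is the directed K-nearest
    neighbor index set of sample k (exactly K entries, self excluded) from
    which A was built before OR-symmetrization.
    """

    A: np.ndarray
    neighbor_sets: list[np.ndarray]
    K: int

    def __post_init__(self) -> None:
        A = np.asarray(self.A)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise InvalidInputError("A must be square")
        if not np.array_equal(A, A.T):
            raise InvalidInputError("A must be symmetric")
        if np.any(np.diag(A) != 0):
            raise InvalidInputError("A must have zero diagonal")

    @property
    def batch_size(self) -> int:
        return self.A.shape[0]


@dataclass
class GcnConfig:
    """Layer plan for the graph convolutional network.

    ``layer_dims`` lists hidden/output widths d_1..d_L (the input width d_0
    is taken from the features); ``None`` means one hidden layer matching
    the feature dimension. The final layer applies no ReLU by default.
    """

    n_layers: int = 1
    layer_dims: tuple[int, ...] | None = None
    add_self_loops: bool = True
    final_activation: bool = False

    def resolved_dims(self, d_in: int) -> tuple[int, ...]:
        if self.layer_dims is None:
            return (d_in,) * self.n_layers
        if len(self.layer_dims) != self.n_layers:
            raise ConfigurationError(
                f"layer_dims has {len(self.layer_dims)} entries for n_layers={self.n_layers}"
            )
        return tuple(self.layer_dims)


@dataclass
class GraphEmbedding:
    """Last-layer graph representations Z, rows aligned with the batch."""

    Z: np.ndarray
    source_ids: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.Z = np.asarray(self.Z, dtype=np.float64)
        if not np.isfinite(self.Z).all():
            raise InvalidInputError("graph embedding contains non-finite entries")


def build_knn_adjacency(features: FeatureBatch | np.ndarray, K: int) -> AdjacencyMatrix:
    """Connect each sample to its K nearest neighbors (Euclidean, self excluded).

    The directed 0/1 matrix (row k has ones exactly at its K nearest
    neighbors) is symmetrized by logical OR. Distance ties are broken by
    lowest index, so duplicate feature rows are handled deterministically.
    """
    F = features.features if isinstance(features, FeatureBatch) else np.asarray(features, dtype=DTYPE)
    if F.ndim != 2:
        raise InvalidInputError("features must be a B x d matrix")
    if not np.isfinite(F).all():
        raise InvalidInputError("features contain non-finite entries")
    B = F.shape[0]
    if not 1 <= K <= B - 1:
        raise InvalidInputError(f"K must satisfy 1 <= K <= B-1 = {B - 1}, got {K}")
    d2 = np.sum((F[:, None, :] - F[None, :, :]) ** 2, axis=-1)
    np.fill_diagonal(d2, np.inf)
    # stable argsort on (distance, index) -> lowest-index tie-break
    order = np.argsort(d2, axis=1, kind="stable")
    neighbor_sets = [np.sort(order[k, :K]) for k in range(B)]
    directed = np.zeros((B, B), dtype=np.int8)
    for k, nbrs in enumerate(neighbor_sets):
        directed[k, nbrs] = 1
    A = np.maximum(directed, directed.T)
    return AdjacencyMatrix(A=A, neighbor_sets=neighbor_sets, K=K)


def normalize_adjacency(A: np.ndarray) -> np.ndarray:
    """Symmetric degree normalization D^{-1/2} A D^{-1/2}.

    The caller applies its self-loop policy first; a zero-degree row is a
    degenerate graph and raises rather than silently producing NaNs.
    """
    A = np.asarray(A, dtype=DTYPE)
    deg = A.sum(axis=1)
    if np.any(deg <= 0):
        bad = np.flatnonzero(deg <= 0)
        raise DegenerateGraphError(
            f"zero-degree node(s) {bad.tolist()}; enable self-loops before normalizing"
        )
    d_inv_sqrt = 1.0 / np.sqrt(deg)
    return A * d_inv_sqrt[:, None] * d_inv_sqrt[None, :]


class GraphConvNet:
    """Graph convolution stack with explicit reverse-mode gradients.

    The normalized adjacency is treated as a constant in the backward pass
    (neighbor selection is discrete); gradients flow to the inputs X^(0)
    and the weights W^(l) only.
    """

    def __init__(self, config: GcnConfig, d_in: int, rng: np.random.Generator) -> None:
        self.config = config
        dims = (d_in,) + config.resolved_dims(d_in)
        self.weights = [
            _he_init(rng, (dims[i], dims[i + 1]), dims[i]) for i in range(len(dims) - 1)
        ]
        self.grads = [np.zeros_like(w) for w in self.weights]
        self.d_in = d_in
        self.d_out = dims[-1]

    def named_params(self) -> dict[str, np.ndarray]:
        return {f"gcn.W{i}": w for i, w in enumerate(self.weights)}

    def named_grads(self) -> dict[str, np.ndarray]:
        return {f"gcn.W{i}": g for i, g in enumerate(self.grads)}

    def zero_grad(self) -> None:
        for g in self.grads:
            g[...] = 0.0

    def prepare_adjacency(self, adjacency: AdjacencyMatrix | np.ndarray) -> np.ndarray:
        A = adjacency.A if isinstance(adjacency, AdjacencyMatrix) else np.asarray(adjacency)
        A = A.astype(DTYPE)
        if self.config.add_self_loops:
            A = A + np.eye(A.shape[0], dtype=DTYPE)
        return normalize_adjacency(A)

    def forward(self, X: np.ndarray, A_hat: np.ndarray):
        if X.shape[1] != self.d_in:
            raise ConfigurationError(
                f"feature dim {X.shape[1]} does not match GCN input dim {self.d_in}"
            )
        caches = []
        out = X
        L = len(self.weights)
        for l, W in enumerate(self.weights):
            prop = A_hat @ out
            pre = prop @ W
            last = l == L - 1
            if last and not self.config.final_activation:
                out, mask = pre, None
            else:
                mask = pre > 0
                out = pre * mask
            caches.append((prop, mask))
        return out, (caches, A_hat)

    def backward(self, dZ: np.ndarray, cache):
        caches, A_hat = cache
        for l in reversed(range(len(self.weights))):
            prop, mask = caches[l]
            dpre = dZ if mask is None else dZ * mask
            self.grads[l] += prop.T @ dpre
            dprop = dpre @ self.weights[l].T
            dZ = A_hat.T @ dprop
        return dZ


def gcn_forward(
    features: FeatureBatch | np.ndarray,
    adjacency: AdjacencyMatrix | np.ndarray,
    gcn: GraphConvNet,
) -> GraphEmbedding:
    """Propagate batch features through the GCN; returns the last-layer Z."""
    F = features.features if isinstance(features, FeatureBatch) else np.asarray(features, dtype=DTYPE)
    ids = features.source_ids if isinstance(features, FeatureBatch) else list(range(len(F)))
    A_hat = gcn.prepare_adjacency(adjacency)
    Z, _ = gcn.forward(F, A_hat)
    return GraphEmbedding(Z=Z, source_ids=ids)
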