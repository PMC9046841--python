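"""Training objectives: graph-center, pseudo-contrastive, transform-invariant.

Three complementary constraints shape the embedding with no manual labels:

* graph-center loss — pulls graph-connected embeddings together,
  (1/2) sum_{k,j} A_kj ||Z_j - Z_k||^2 over the symmetrized zero-diagonal
  adjacency (self-loops excluded from the loss);
* pseudo-contrastive loss — a margin contrastive loss driven by pairwise
  pseudo-labels l(k,j) = 1 iff the two samples share more than lambda of
  their K nearest neighbors;
* transform-invariant loss — the mean unsquared Euclidean distance between
  the embedding of each image and that of a randomly transformed copy.

The combined objective is  L = L_pc + alpha * L_gc + beta * L_ti.

Each loss has a public scalar form and a ``*_grad`` companion returning the
gradient with respect to Z; adjacency and pseudo-labels are discrete
selections and receive no gradient.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .exceptions import ConfigurationError, InvalidInputError, NumericError
from .graph import AdjacencyMatrix, GraphEmbedding


@dataclass
class PairwiseLabels:
    """Estimated 0/1 same-class indicators for every batch pair.

    The diagonal is undefined and excluded from all losses. Symmetry holds
    by construction (set intersection is symmetric).
    """

    l: np.ndarray  # (B, B) int8
    lam: int

    def __post_init__(self) -> None:
        l = np.asarray(self.l)
        if l.ndim != 2 or l.shape[0] != l.shape[1]:
            raise InvalidInputError("pairwise label matrix must be square")
        if not np.array_equal(l, l.T):
            raise InvalidInputError("pairwise label matrix must be symmetric")


@dataclass(frozen=True)
class LossWeights:
    """Balance parameters of the combined objective.

    alpha weights the graph-center term, beta the transform-invariant term;
    margin is the hinge margin m of the contrastive loss.
    """

    alpha: float = 0.1
    beta: float = 0.1
    margin: float = 1.0

    def __post_init__(self) -> None:
        if self.margin <= 0:
            raise ConfigurationError("margin must be positive")
        if self.alpha < 0 or self.beta < 0:
            raise ConfigurationError("alpha and beta must be non-negative")


@dataclass(frozen=True)
class LossReport:
    """Component and combined loss values for one step."""

    pc: float
    gc: float
    ti: float
    total: float


def _z(Z) -> np.ndarray:
    Z = Z.Z if isinstance(Z, GraphEmbedding) else np.asarray(Z, dtype=np.float64)
    if Z.ndim != 2:
        raise InvalidInputError("Z must be a B x d matrix")
    return Z


# ---------------------------------------------------------------------------
# graph-center loss


def graph_center_loss(Z, A) -> float:
    """(1/2) sum_{k,j} A_kj ||Z_j - Z_k||^2 over the zero-diagonal adjacency."""
    Zm = _z(Z)
    Am = A.A if isinstance(A, AdjacencyMatrix) else np.asarray(A)
    if Am.shape[0] != Zm.shape[0] or Am.shape[0] != Am.shape[1]:
        raise InvalidInputError(
            f"adjacency {Am.shape} does not align with embedding rows {Zm.shape[0]}"
        )
    Am = Am.astype(np.float64)
    d2 = np.sum((Zm[:, None, :] - Zm[None, :, :]) ** 2, axis=-1)
    return float(0.5 * np.sum(Am * d2))


def graph_center_loss_grad(Z, A) -> np.ndarray:
    """d/dZ of the graph-center loss; for symmetric A this is
    2 (D Z - A Z) with D the degree matrix."""
    Zm = _z(Z)
    Am = (A.A if isinstance(A, AdjacencyMatrix) else np.asarray(A)).astype(np.float64)
    sym = Am + Am.T  # handles non-symmetric input too; = 2A when symmetric
    deg = sym.sum(axis=1)
    return deg[:, None] * Zm - sym @ Zm


# ---------------------------------------------------------------------------
# pseudo-label estimation


def estimate_pairwise_labels(
    neighbor_sets: list[np.ndarray], lam: int
) -> PairwiseLabels:
    """l(k,j) = 1 iff |K_k ∩ K_j| > lambda (strict), for all k != j.

    Neighbor sets exclude the samples themselves. lambda above K labels
    every pair 0 and emits a configuration warning.
    """
    if lam < 0:
        raise ConfigurationError("lambda must be non-negative")
    B = len(neighbor_sets)
    K = len(neighbor_sets[0]) if B else 0
    if lam > K:
        warnings.warn(
            f"lambda={lam} exceeds K={K}; every pair will be labeled 0",
            stacklevel=2,
        )
    sets = [set(int(i) for i in s) for s in neighbor_sets]
    l = np.zeros((B, B), dtype=np.int8)
    for k in range(B):
        for j in range(k + 1, B):
            if len(sets[k] & sets[j]) > lam:
                l[k, j] = l[j, k] = 1
    return PairwiseLabels(l=l, lam=lam)


# ---------------------------------------------------------------------------
# pseudo-contrastive loss


def _pairwise_dists(Zm: np.ndarray) -> np.ndarray:
    d2 = np.sum((Zm[:, None, :] - Zm[None, :, :]) ** 2, axis=-1)
    return np.sqrt(np.maximum(d2, 0.0))


def pseudo_contrastive_loss(Z, labels: PairwiseLabels, margin: float) -> float:
    """Margin contrastive loss over all unordered batch pairs.

    (1/(2 N_pairs)) sum_pairs [ l d^2 + (1-l) max(m-d, 0)^2 ] with d the
    Euclidean distance between the pair's embeddings and N_pairs the number
    of unordered pairs summed.
    """
    if margin <= 0:
        raise ConfigurationError("margin must be positive")
    Zm = _z(Z)
    B = Zm.shape[0]
    lmat = labels.l if isinstance(labels, PairwiseLabels) else np.asarray(labels)
    if lmat.shape != (B, B):
        raise InvalidInputError("labels must cover all batch pairs")
    if B < 2:
        return 0.0
    d = _pairwise_dists(Zm)
    hinge = np.maximum(margin - d, 0.0)
    per_pair = lmat * d**2 + (1 - lmat) * hinge**2
    iu = np.triu_indices(B, k=1)
    n_pairs = len(iu[0])
    return float(per_pair[iu].sum() / (2.0 * n_pairs))


def pseudo_contrastive_loss_grad(Z, labels: PairwiseLabels, margin: float) -> np.ndarray:
    """Gradient of the pseudo-contrastive loss with respect to Z."""
    if margin <= 0:
        raise ConfigurationError("margin must be positive")
    Zm = _z(Z)
    B = Zm.shape[0]
    if B < 2:
        return np.zeros_like(Zm)
    lmat = (labels.l if isinstance(labels, PairwiseLabels) else np.asarray(labels)).astype(
        np.float64
    )
    diff = Zm[:, None, :] - Zm[None, :, :]  # (B, B, d), row k minus row j
    d = _pairwise_dists(Zm)
    hinge = np.maximum(margin - d, 0.0)
    safe_d = np.where(d > 0, d, 1.0)
    # per ordered pair (k, j): l * diff  -  (1-l) * hinge * diff / d
    coeff = lmat - (1 - lmat) * hinge / safe_d
    np.fill_diagonal(coeff, 0.0)
    n_pairs = B * (B - 1) // 2
    # d/dZ_k of (1/(2N)) sum_{k<j} [l d^2 + (1-l) h^2]: the 1/2 cancels the
    # chain-rule 2, and each unordered pair containing k appears once in j
    return (coeff[:, :, None] * diff).sum(axis=1) / n_pairs


# ---------------------------------------------------------------------------
# transform-invariant loss


def transform_invariant_loss(Z, Z_transformed, *, squared: bool = False) -> float:
    """(1/B) sum_k ||Z_k - Z'_k|| (unsquared norm by default, as the model
    is specified; a squared variant is available for experimentation)."""
    Zm, Zt = _z(Z), _z(Z_transformed)
    if Zm.shape != Zt.shape:
        raise InvalidInputError(f"row mismatch: {Zm.shape} vs {Zt.shape}")
    norms = np.linalg.norm(Zm - Zt, axis=1)
    if squared:
        norms = norms**2
    return float(norms.mean())


def transform_invariant_loss_grad(
    Z, Z_transformed, *, squared: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Gradients with respect to (Z, Z'); zero rows where the two coincide."""
    Zm, Zt = _z(Z), _z(Z_transformed)
    if Zm.shape != Zt.shape:
        raise InvalidInputError(f"row mismatch: {Zm.shape} vs {Zt.shape}")
    B = Zm.shape[0]
    diff = Zm - Zt
    if squared:
        g = 2.0 * diff / B
    else:
        norms = np.linalg.norm(diff, axis=1, keepdims=True)
        g = np.where(norms > 0, diff / np.maximum(norms, 1e-300), 0.0) / B
    return g, -g


# ---------------------------------------------------------------------------
# combined objective


def total_loss(pc: float, gc: float, ti: float, weights: LossWeights) -> LossReport:
    """Combine components:  total = pc + alpha * gc + beta * ti."""
    for name, v in (("pc", pc), ("gc", gc), ("ti", ti)):
        if not np.isfinite(v):
            raise NumericError(f"loss component {name!r} is non-finite: {v}")
    return LossReport(
        pc=float(pc),
        gc=float(gc),
        ti=float(ti),
        total=float(pc + weights.alpha * gc + weights.beta * ti),
    )
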