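"""Per-image feature extraction and stochastic input transformations.

The convolutional backbone maps each RGB image independently to a
``feature_dim`` vector (weight sharing across the batch, order-preserving).
Two architectures are available: ``small_conv``, a 3-block network sized for
CPU-scale experiments and used throughout the tests, and ``residual_50``, a
normalization-free bottleneck residual stack mirroring the usual 50-layer
layout for users who want the full-scale backbone. The method itself is
architecture-agnostic.

The transformation family T(.) used by the invariance loss lives here too:
label-preserving image transforms (random rotation, optional horizontal
flip) sampled per call from an explicit RNG.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from ._nn import (
    AvgPool2,
    Conv2d,
    GlobalAvgPool,
    Linear,
    ReLU,
    Residual,
    Sequential,
)
from .exceptions import ConfigurationError, InvalidInputError


@dataclass(frozen=True)
class EncoderConfig:
    """Backbone choice and output dimensionality.

    ``normalize_features`` optionally L2-normalizes feature rows before
    graph construction (off by default).
    """

    architecture: str = "small_conv"
    feature_dim: int = 16
    #: conv channel widths of the three small_conv blocks
    channels: tuple[int, int, int] = (8, 16, 32)
    normalize_features: bool = False
    #: per-image standardization (subtract mean, divide by std) at the input
    #: boundary; removes brightness/contrast nuisance before feature learning
    standardize_input: bool = True

    def __post_init__(self) -> None:
        if self.architecture not in ("small_conv", "residual_50"):
            raise ConfigurationError(f"unknown architecture {self.architecture!r}")
        if self.feature_dim < 2:
            raise ConfigurationError("feature_dim must be >= 2")


@dataclass
class FeatureBatch:
    """Per-image feature vectors for one mini-batch, rows aligned to inputs."""

    features: np.ndarray  # (B, feature_dim)
    source_ids: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=np.float64)
        if self.features.ndim != 2:
            raise InvalidInputError("features must be a B x d matrix")
        if not np.isfinite(self.features).all():
            raise InvalidInputError("features contain non-finite entries")

    @property
    def batch_size(self) -> int:
        return self.features.shape[0]


@dataclass(frozen=True)
class TransformSpec:
    """Family of label-preserving input transformations.

    Rotation angles (degrees) are sampled uniformly from
    ``rotation_range``; ``hflip`` adds a 50% horizontal flip. An empty
    family (zero-width rotation range, no flip) is allowed only via
    ``identity()`` — it is useful for ablations.
    """

    rotation_range: tuple[float, float] = (-180.0, 180.0)
    hflip: bool = False

    @classmethod
    def identity(cls) -> "TransformSpec":
        return cls(rotation_range=(0.0, 0.0), hflip=False)

    def __post_init__(self) -> None:
        lo, hi = self.rotation_range
        if hi < lo:
            raise ConfigurationError("rotation_range must be (low, high) with low <= high")


def apply_transform(
    image: np.ndarray, spec: TransformSpec, rng: np.random.Generator
) -> np.ndarray:
    """Sample T from the family and return T(image); shape is preserved.

    Rotation uses bilinear interpolation about the image center with
    zero fill outside the frame — grade semantics (lesion content) are
    unchanged, only viewpoint.
    """
    if spec is None:
        raise ConfigurationError("transform family is empty")
    img = np.asarray(image, dtype=np.float64)
    angle = float(rng.uniform(*spec.rotation_range))
    flip = spec.hflip and rng.uniform() < 0.5
    out = img
    if flip:
        out = out[:, ::-1, :].copy()
    if angle != 0.0:
        out = ndimage.rotate(
            out, angle, axes=(1, 0), reshape=False, order=1, mode="constant", cval=0.0
        )
        out = np.clip(out, 0.0, 1.0)
    return out


def _build_small_conv(
    feature_dim: int, channels: tuple[int, int, int], rng: np.random.Generator
) -> Sequential:
    c1, c2, c3 = channels
    return Sequential(
        [
            Conv2d(3, c1, rng=rng),
            ReLU(),
            AvgPool2(),
            Conv2d(c1, c2, rng=rng),
            ReLU(),
            AvgPool2(),
            Conv2d(c2, c3, rng=rng),
            ReLU(),
            AvgPool2(),
            GlobalAvgPool(),
            Linear(c3, feature_dim, rng=rng),
        ]
    )


def _bottleneck(c_in: int, c_mid: int, stride: int, rng: np.random.Generator) -> Residual:
    c_out = 4 * c_mid
    body = Sequential(
        [
            Conv2d(c_in, c_mid, ksize=1, stride=1, pad=0, rng=rng),
            ReLU(),
            Conv2d(c_mid, c_mid, ksize=3, stride=stride, pad=1, rng=rng),
            ReLU(),
            Conv2d(c_mid, c_out, ksize=1, stride=1, pad=0, rng=rng),
        ]
    )
    proj = None
    if stride != 1 or c_in != c_out:
        proj = Conv2d(c_in, c_out, ksize=1, stride=stride, pad=0, rng=rng)
    return Residual(body, proj)


def _build_residual_50(feature_dim: int, rng: np.random.Generator) -> Sequential:
    """Bottleneck residual stack with the standard [3, 4, 6, 3] stage plan.

    Batch normalization is omitted (the stack is trained at desk scale in
    float64 with He initialization); this keeps the backward pass exact and
    the checkpoint format simple.
    """
    layers: list = [Conv2d(3, 64, ksize=7, stride=2, pad=3, rng=rng), ReLU(), AvgPool2()]
    c_in = 64
    for c_mid, n_blocks, first_stride in ((64, 3, 1), (128, 4, 2), (256, 6, 2), (512, 3, 2)):
        for b in range(n_blocks):
            stride = first_stride if b == 0 else 1
            layers.append(_bottleneck(c_in, c_mid, stride, rng))
            layers.append(ReLU())
            c_in = 4 * c_mid
    layers += [GlobalAvgPool(), Linear(c_in, feature_dim, rng=rng)]
    return Sequential(layers)


class ConvEncoder:
    """Configurable convolutional backbone r(.; theta).

    ``forward``/``backward`` expose the reverse-mode interface used by the
    trainer; :func:`encode_batch` is the user-facing functional wrapper.
    """

    def __init__(self, config: EncoderConfig, rng: np.random.Generator) -> None:
        self.config = config
        if config.architecture == "small_conv":
            self.net = _build_small_conv(config.feature_dim, tuple(config.channels), rng)
        else:
            self.net = _build_residual_50(config.feature_dim, rng)

    # -- parameter plumbing -------------------------------------------------
    def named_params(self) -> dict[str, np.ndarray]:
        return self.net.named_params("enc.")

    def named_grads(self) -> dict[str, np.ndarray]:
        return self.net.named_grads("enc.")

    def zero_grad(self) -> None:
        self.net.zero_grad()

    # -- forward / backward -------------------------------------------------
    @staticmethod
    def to_input(images: list[np.ndarray]) -> np.ndarray:
        """Stack channel-last [0,1] images into a (B, 3, H, W) float64 array."""
        if len(images) == 0:
            raise InvalidInputError("empty image batch")
        shapes = {im.shape for im in images}
        if len(shapes) != 1:
            raise InvalidInputError(f"images have mixed shapes: {sorted(shapes)}")
        x = np.stack([np.asarray(im, dtype=np.float64) for im in images])
        if x.ndim != 4 or x.shape[-1] != 3:
            raise InvalidInputError("images must be (H, W, 3) RGB arrays")
        if not np.isfinite(x).all():
            raise InvalidInputError("images contain non-finite pixel values")
        return x.transpose(0, 3, 1, 2)

    def forward(self, x: np.ndarray, train: bool = True):
        if self.config.standardize_input:
            mean = x.mean(axis=(1, 2, 3), keepdims=True)
            std = np.maximum(x.std(axis=(1, 2, 3), keepdims=True), 1e-6)
            x = (x - mean) / std  # constants w.r.t. parameters: no grad needed
        f, cache = self.net.forward(x, train)
        if self.config.normalize_features:
            norms = np.linalg.norm(f, axis=1, keepdims=True)
            safe = np.maximum(norms, 1e-12)
            cache = (cache, f, safe)
            return f / safe, cache
        return f, (cache, None, None)

    def backward(self, df: np.ndarray, cache):
        inner, f, safe = cache
        if self.config.normalize_features:
            # d(f / ||f||) — project out the radial component
            fn = f / safe
            df = (df - fn * (df * fn).sum(axis=1, keepdims=True)) / safe
        return self.net.backward(df, inner)


def encode_batch(
    images: list[np.ndarray],
    encoder: ConvEncoder,
    mode: str = "eval",
    source_ids: list | None = None,
) -> FeatureBatch:
    """Map a batch of images to per-image feature vectors (order-preserving).

    ``mode`` is 'train' or 'eval'; the architectures here have no stochastic
    layers, so eval-mode determinism is the identity guarantee that repeated
    calls on identical input give identical output.
    """
    if mode not in ("train", "eval"):
        raise InvalidInputError(f"mode must be 'train' or 'eval', got {mode!r}")
    x = ConvEncoder.to_input(images)
    f, _ = encoder.forward(x, train=(mode == "train"))
    return FeatureBatch(features=f, source_ids=source_ids or list(range(len(images))))
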