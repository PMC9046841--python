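"""Minimal reverse-mode neural-network layers in numpy.

Everything runs in float64 so that analytic gradients can be validated
against central finite differences to tight relative tolerances. Layers are
stateless with respect to activations: ``forward`` returns ``(y, cache)``
and ``backward(dy, cache)`` returns ``dx`` while accumulating parameter
gradients into ``self.grads``. This lets one network be run twice per step
(original and transformed view) before a single backward/update cycle.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .exceptions import ConfigurationError

DTYPE = np.float64


class Layer:
    """Base layer: parameter dict + gradient dict, both name → ndarray."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool = True):
        raise NotImplementedError

    def backward(self, dy: np.ndarray, cache):
        raise NotImplementedError

    def zero_grad(self) -> None:
        for k, v in self.params.items():
            self.grads[k] = np.zeros_like(v)


def _he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(DTYPE)


class Conv2d(Layer):
    """2-D convolution (cross-correlation) with 'same'-style zero padding.

    Input layout (B, C, H, W). Implemented by im2col + matmul; the backward
    scatter runs over the k*k kernel offsets, which is fast for small kernels.
    """

    def __init__(self, c_in: int, c_out: int, ksize: int = 3, stride: int = 1,
                 pad: int | None = None, *, rng: np.random.Generator) -> None:
        super().__init__()
        self.c_in, self.c_out, self.k, self.stride = c_in, c_out, ksize, stride
        self.pad = (ksize - 1) // 2 if pad is None else pad
        fan_in = c_in * ksize * ksize
        self.params["W"] = _he_init(rng, (c_out, fan_in), fan_in)
        # small random biases: zero biases put every all-zero input patch
        # exactly on the ReLU kink, which breaks finite-difference checks
        self.params["b"] = rng.uniform(-0.01, 0.01, size=c_out).astype(DTYPE)
        self.zero_grad()

    def _cols(self, xp: np.ndarray, h_out: int, w_out: int) -> np.ndarray:
        # (B, C, Hp, Wp) -> (B, h_out*w_out, C*k*k)
        win = sliding_window_view(xp, (self.k, self.k), axis=(2, 3))
        win = win[:, :, :: self.stride, :: self.stride]
        b = xp.shape[0]
        return win.transpose(0, 2, 3, 1, 4, 5).reshape(b, h_out * w_out, -1)

    def forward(self, x: np.ndarray, train: bool = True):
        b, c, h, w = x.shape
        p = self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        h_out = (h + 2 * p - self.k) // self.stride + 1
        w_out = (w + 2 * p - self.k) // self.stride + 1
        cols = self._cols(xp, h_out, w_out)
        y = cols @ self.params["W"].T + self.params["b"]
        y = y.transpose(0, 2, 1).reshape(b, self.c_out, h_out, w_out)
        return y, (cols, x.shape)

    def backward(self, dy: np.ndarray, cache):
        cols, x_shape = cache
        b, c, h, w = x_shape
        p, k, s = self.pad, self.k, self.stride
        h_out, w_out = dy.shape[2], dy.shape[3]
        dy_flat = dy.reshape(b, self.c_out, -1).transpose(0, 2, 1)  # (B, HW, Cout)
        self.grads["W"] += np.einsum("bpc,bpf->cf", dy_flat, cols)
        self.grads["b"] += dy_flat.sum(axis=(0, 1))
        dcols = dy_flat @ self.params["W"]  # (B, HW, C*k*k)
        dcols = dcols.reshape(b, h_out, w_out, c, k, k)
        dxp = np.zeros((b, c, h + 2 * p, w + 2 * p), dtype=DTYPE)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i : i + s * h_out : s, j : j + s * w_out : s] += (
                    dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
                )
        return dxp[:, :, p : p + h, p : p + w] if p else dxp


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = True):
        mask = x > 0
        return x * mask, mask

    def backward(self, dy: np.ndarray, cache):
        return dy * cache


class AvgPool2(Layer):
    """2x2 average pooling, stride 2; truncates odd trailing rows/cols."""

    def forward(self, x: np.ndarray, train: bool = True):
        b, c, h, w = x.shape
        h2, w2 = h // 2, w // 2
        xt = x[:, :, : 2 * h2, : 2 * w2].reshape(b, c, h2, 2, w2, 2)
        return xt.mean(axis=(3, 5)), (h, w)

    def backward(self, dy: np.ndarray, cache):
        h, w = cache
        b, c, h2, w2 = dy.shape
        dx = np.zeros((b, c, h, w), dtype=DTYPE)
        up = np.repeat(np.repeat(dy, 2, axis=2), 2, axis=3) / 4.0
        dx[:, :, : 2 * h2, : 2 * w2] = up
        return dx


class GlobalAvgPool(Layer):
    """(B, C, H, W) -> (B, C) spatial mean."""

    def forward(self, x: np.ndarray, train: bool = True):
        return x.mean(axis=(2, 3)), x.shape

    def backward(self, dy: np.ndarray, cache):
        b, c, h, w = cache
        return np.broadcast_to(dy[:, :, None, None], (b, c, h, w)) / (h * w)


class Linear(Layer):
    def __init__(self, d_in: int, d_out: int, *, rng: np.random.Generator) -> None:
        super().__init__()
        self.params["W"] = _he_init(rng, (d_in, d_out), d_in)
        self.params["b"] = rng.uniform(-0.01, 0.01, size=d_out).astype(DTYPE)
        self.zero_grad()

    def forward(self, x: np.ndarray, train: bool = True):
        return x @ self.params["W"] + self.params["b"], x

    def backward(self, dy: np.ndarray, cache):
        x = cache
        self.grads["W"] += x.T @ dy
        self.grads["b"] += dy.sum(axis=0)
        return dy @ self.params["W"].T


class Sequential(Layer):
    def __init__(self, layers: list[Layer]) -> None:
        super().__init__()
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = True):
        caches = []
        for layer in self.layers:
            x, c = layer.forward(x, train)
            caches.append(c)
        return x, caches

    def backward(self, dy: np.ndarray, caches):
        for layer, c in zip(reversed(self.layers), reversed(caches)):
            dy = layer.backward(dy, c)
        return dy

    def zero_grad(self) -> None:
        for layer in self.layers:
            layer.zero_grad()

    def named_params(self, prefix: str = "") -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for i, layer in enumerate(self.layers):
            if isinstance(layer, Sequential):
                out.update(layer.named_params(f"{prefix}{i}."))
            else:
                for k, v in layer.params.items():
                    out[f"{prefix}{i}.{k}"] = v
        return out

    def named_grads(self, prefix: str = "") -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for i, layer in enumerate(self.layers):
            if isinstance(layer, Sequential):
                out.update(layer.named_grads(f"{prefix}{i}."))
            else:
                for k, v in layer.grads.items():
                    out[f"{prefix}{i}.{k}"] = v
        return out


class Residual(Layer):
    """y = f(x) + g(x) with f a Sequential body and g an optional projection."""

    def __init__(self, body: Sequential, projection: Layer | None = None) -> None:
        super().__init__()
        self.body = body
        self.projection = projection

    def forward(self, x: np.ndarray, train: bool = True):
        y, cb = self.body.forward(x, train)
        if self.projection is not None:
            sc, cp = self.projection.forward(x, train)
        else:
            sc, cp = x, None
        if y.shape != sc.shape:
            raise ConfigurationError(
                f"residual branch shape {y.shape} != shortcut {sc.shape}"
            )
        return y + sc, (cb, cp)

    def backward(self, dy: np.ndarray, cache):
        cb, cp = cache
        dx = self.body.backward(dy, cb)
        if self.projection is not None:
            dx = dx + self.projection.backward(dy, cp)
        else:
            dx = dx + dy
        return dx

    def zero_grad(self) -> None:
        self.body.zero_grad()
        if self.projection is not None:
            self.projection.zero_grad()

    # expose parameters through Sequential's discovery
    @property
    def params(self):  # type: ignore[override]
        out = {}
        for k, v in self.body.named_params("body.").items():
            out[k] = v
        if self.projection is not None:
            for k, v in self.projection.params.items():
                out[f"proj.{k}"] = v
        return out

    @params.setter
    def params(self, value):  # Layer.__init__ assigns {}; ignore
        pass

    @property
    def grads(self):  # type: ignore[override]
        out = {}
        for k, v in self.body.named_grads("body.").items():
            out[k] = v
        if self.projection is not None:
            for k, v in self.projection.grads.items():
                out[f"proj.{k}"] = v
        return out

    @grads.setter
    def grads(self, value):
        pass


class SGD:
    """Stochastic gradient descent with classical momentum.

    Velocity buffers are keyed by parameter name so optimizer state can be
    checkpointed and restored exactly.
    """

    name = "sgd"

    def __init__(self, lr: float = 0.01, momentum: float = 0.9) -> None:
        if lr <= 0:
            raise ConfigurationError("learning rate must be positive")
        self.lr = lr
        self.momentum = momentum
        self.velocity: dict[str, np.ndarray] = {}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        for name, p in params.items():
            g = grads[name]
            v = self.velocity.get(name)
            if v is None:
                v = np.zeros_like(p)
            v = self.momentum * v - self.lr * g
            self.velocity[name] = v
            p += v

    def state_arrays(self) -> dict[str, np.ndarray]:
        return dict(self.velocity)

    def load_state_arrays(self, arrays: dict[str, np.ndarray]) -> None:
        self.velocity = {k: v.copy() for k, v in arrays.items()}


class Adam:
    """Adam optimizer; per-parameter adaptive step sizes make it robust to
    the very different scales of the loss components."""

    name = "adam"

    def __init__(self, lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8) -> None:
        if lr <= 0:
            raise ConfigurationError("learning rate must be positive")
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for name, p in params.items():
            g = grads[name]
            m = self.m.get(name)
            if m is None:
                m = np.zeros_like(p)
                self.v[name] = np.zeros_like(p)
            v = self.v[name]
            m = b1 * m + (1 - b1) * g
            v = b2 * v + (1 - b2) * g * g
            self.m[name], self.v[name] = m, v
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def state_arrays(self) -> dict[str, np.ndarray]:
        out = {f"m~{k}": v for k, v in self.m.items()}
        out.update({f"v~{k}": v for k, v in self.v.items()})
        out["t~"] = np.array([self.t], dtype=np.int64)
        return out

    def load_state_arrays(self, arrays: dict[str, np.ndarray]) -> None:
        self.m, self.v = {}, {}
        for k, arr in arrays.items():
            if k == "t~":
                self.t = int(arr[0])
            elif k.startswith("m~"):
                self.m[k[2:]] = arr.copy()
            elif k.startswith("v~"):
                self.v[k[2:]] = arr.copy()
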