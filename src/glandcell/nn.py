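"""Minimal CPU neural-network engine used by the gland/stroma classifier.

Implements exactly the layer vocabulary the GlandNet topology needs --
3x3 same-padding convolutions, 2x2 max pooling, global average pooling,
dense layers, additive Gaussian-noise layers -- with hand-written
backpropagation and an Adam optimizer.  Arrays are channel-last
``(N, H, W, C)`` float32 throughout; all randomness flows through an
explicit ``numpy.random.Generator`` so training runs are reproducible.
"""

from __future__ import annotations

import json
from typing import Sequence

import numpy as np

__all__ = [
    "Conv3x3",
    "MaxPool2",
    "GlobalAvgPool",
    "Dense",
    "GaussianNoise",
    "Sequential",
    "Adam",
    "softmax",
    "weighted_cross_entropy",
    "softmax_ce_grad",
]

_EPS_LOG = 1e-12


def softmax(logits: np.ndarray) -> np.ndarray:
    """Row-wise softmax, stabilized by max-subtraction.

    Accepts a single logit vector or a ``(N, K)`` batch; output rows are
    strictly positive and sum to 1 within float tolerance.
    """
    z = np.asarray(logits, dtype=np.float64)
    if z.size == 0:
        raise ValueError("softmax of an empty logit vector is undefined")
    if not np.all(np.isfinite(z)):
        raise ValueError("softmax requires finite logits")
    single = z.ndim == 1
    if single:
        z = z[None, :]
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=1, keepdims=True)
    return p[0] if single else p


def weighted_cross_entropy(
    true_onehot: np.ndarray,
    probs: np.ndarray,
    class_weights: np.ndarray | Sequence[float],
) -> float:
    """Weighted categorical cross-entropy ``-sum_i w_i * y_i * log(p_i)``.

    ``true_onehot`` and ``probs`` may be single vectors or ``(N, K)``
    batches (batches are averaged).  Probabilities are clipped to
    ``[eps, 1-eps]`` before the log.
    """
    y = np.atleast_2d(np.asarray(true_onehot, dtype=np.float64))
    p = np.atleast_2d(np.asarray(probs, dtype=np.float64))
    w = np.asarray(class_weights, dtype=np.float64)
    if y.shape != p.shape or w.shape != (y.shape[1],):
        raise ValueError(
            f"shape mismatch: onehot {y.shape}, probs {p.shape}, weights {w.shape}"
        )
    if np.any(w <= 0):
        raise ValueError("class weights must be positive")
    p = np.clip(p, _EPS_LOG, 1.0 - _EPS_LOG)
    per_sample = -(w[None, :] * y * np.log(p)).sum(axis=1)
    return float(per_sample.mean())


def softmax_ce_grad(
    logits: np.ndarray,
    true_onehot: np.ndarray,
    class_weights: np.ndarray,
    sample_weights: np.ndarray | None = None,
) -> tuple[float, np.ndarray]:
    """Loss and d(loss)/d(logits) for softmax + weighted CE in one pass.

    For the weighted loss the gradient at the logits is
    ``w_c * (p - y) / N`` where ``w_c`` is the weight of each sample's
    true class; optional per-sample weights (soft pseudo-labels)
    multiply on top.
    """
    p = softmax(logits)
    n = logits.shape[0]
    w_true = (true_onehot * class_weights[None, :]).sum(axis=1)  # (N,)
    if sample_weights is not None:
        w_true = w_true * np.asarray(sample_weights, dtype=np.float64)
    pc = np.clip(p, _EPS_LOG, 1.0 - _EPS_LOG)
    loss = float((w_true * -(true_onehot * np.log(pc)).sum(axis=1)).mean())
    grad = (w_true[:, None] * (p - true_onehot) / n).astype(np.float32)
    return loss, grad


def _he_normal(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)


class Layer:
    """Base layer: ``params()`` yields (name, array) pairs; grads mirror them."""

    kind = "layer"
    has_weights = False

    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []

    def forward(self, x: np.ndarray, training: bool, rng: np.random.Generator | None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


LEAKY_SLOPE = 0.1  # keeps narrow scaled stacks trainable (no dead-feature collapse)


class Conv3x3(Layer):
    """3x3 convolution, stride 1, zero same-padding, leaky-ReLU activation."""

    kind = "conv"
    has_weights = True

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        self.c_in, self.c_out = c_in, c_out
        self.W = _he_normal(rng, (3, 3, c_in, c_out), fan_in=9 * c_in)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    @property
    def n_params(self) -> int:
        return self.W.size + self.b.size

    def forward(self, x, training, rng):
        n, h, w, _ = x.shape
        xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
        y = np.broadcast_to(self.b, (n, h, w, self.c_out)).copy()
        flat = y.reshape(-1, self.c_out)
        for i in range(3):
            for j in range(3):
                win = xp[:, i : i + h, j : j + w, :].reshape(-1, self.c_in)
                flat += win @ self.W[i, j]
        self._xp = xp
        self._scale = np.where(flat > 0, np.float32(1.0), np.float32(LEAKY_SLOPE))
        flat *= self._scale
        return y

    def backward(self, dout):
        n, h, w, _ = dout.shape
        dflat = dout.reshape(-1, self.c_out) * self._scale
        self.db[...] = dflat.sum(axis=0)
        dxp = np.zeros_like(self._xp)
        for i in range(3):
            for j in range(3):
                win = self._xp[:, i : i + h, j : j + w, :].reshape(-1, self.c_in)
                self.dW[i, j] = win.T @ dflat
                dxp[:, i : i + h, j : j + w, :] += (dflat @ self.W[i, j].T).reshape(
                    n, h, w, self.c_in
                )
        self._xp = None
        self._mask = None
        return dxp[:, 1:-1, 1:-1, :]


class MaxPool2(Layer):
    """2x2 max pooling, stride 2. Deterministic argmax tie-break (first index)."""

    kind = "maxpool"

    def forward(self, x, training, rng):
        n, h, w, c = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"MaxPool2 needs even spatial dims, got {h}x{w}")
        xr = (
            x.reshape(n, h // 2, 2, w // 2, 2, c)
            .transpose(0, 1, 3, 5, 2, 4)
            .reshape(n, h // 2, w // 2, c, 4)
        )
        self._idx = xr.argmax(axis=-1)
        self._shape = (n, h, w, c)
        return np.take_along_axis(xr, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, dout):
        n, h, w, c = self._shape
        dxr = np.zeros((n, h // 2, w // 2, c, 4), dtype=dout.dtype)
        np.put_along_axis(dxr, self._idx[..., None], dout[..., None], axis=-1)
        return (
            dxr.reshape(n, h // 2, w // 2, c, 2, 2)
            .transpose(0, 1, 4, 2, 5, 3)
            .reshape(n, h, w, c)
        )


class GlobalAvgPool(Layer):
    """Spatial mean: (N, H, W, C) -> (N, C)."""

    kind = "gap"

    def forward(self, x, training, rng):
        self._shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, dout):
        n, h, w, c = self._shape
        return np.broadcast_to(dout[:, None, None, :] / (h * w), (n, h, w, c)).astype(
            dout.dtype
        )


class Dense(Layer):
    kind = "dense"
    has_weights = True

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator, relu: bool = True):
        self.d_in, self.d_out, self.relu = d_in, d_out, relu
        self.W = _he_normal(rng, (d_in, d_out), fan_in=d_in)
        self.b = np.zeros(d_out, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    @property
    def n_params(self) -> int:
        return self.W.size + self.b.size

    def forward(self, x, training, rng):
        self._x = x
        y = x @ self.W + self.b
        if self.relu:
            self._scale = np.where(y > 0, np.float32(1.0), np.float32(LEAKY_SLOPE))
            y *= self._scale
        return y

    def backward(self, dout):
        if self.relu:
            dout = dout * self._scale
        self.dW[...] = self._x.T @ dout
        self.db[...] = dout.sum(axis=0)
        dx = dout @ self.W.T
        self._x = None
        return dx


class GaussianNoise(Layer):
    """Additive zero-mean Gaussian noise, active only in training mode."""

    kind = "noise"

    def __init__(self, sigma: float):
        if sigma < 0:
            raise ValueError("noise sigma must be >= 0")
        self.sigma = float(sigma)

    def forward(self, x, training, rng):
        if training and self.sigma > 0:
            if rng is None:
                raise ValueError("training-mode noise needs an rng")
            return x + rng.normal(0.0, self.sigma, size=x.shape).astype(x.dtype)
        return x

    def backward(self, dout):
        return dout


class Sequential:
    """A feed-forward stack with explicit forward/backward passes."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(
        self, x: np.ndarray, training: bool = False, rng: np.random.Generator | None = None
    ) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training, rng)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params()]

    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads()]

    @property
    def weight_layers(self) -> list[Layer]:
        return [l for l in self.layers if l.has_weights]

    @property
    def layer_kinds(self) -> list[str]:
        return [l.kind for l in self.layers]

    @property
    def n_params(self) -> int:
        return sum(p.size for p in self.params())

    # -- serialization -----------------------------------------------------
    def state_arrays(self) -> dict[str, np.ndarray]:
        out = {}
        for i, layer in enumerate(self.layers):
            for j, p in enumerate(layer.params()):
                out[f"layer{i:02d}_p{j}"] = p
        return out

    def load_state_arrays(self, arrays: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self.layers):
            for j, p in enumerate(layer.params()):
                key = f"layer{i:02d}_p{j}"
                src = arrays[key]
                if src.shape != p.shape:
                    raise ValueError(f"checkpoint shape mismatch at {key}")
                p[...] = src

    def topology_json(self) -> str:
        desc = []
        for layer in self.layers:
            entry: dict = {"kind": layer.kind}
            if isinstance(layer, Conv3x3):
                entry.update(c_in=layer.c_in, c_out=layer.c_out)
            elif isinstance(layer, Dense):
                entry.update(d_in=layer.d_in, d_out=layer.d_out, relu=layer.relu)
            elif isinstance(layer, GaussianNoise):
                entry.update(sigma=layer.sigma)
            desc.append(entry)
        return json.dumps(desc, indent=1)


class Adam:
    """Adam with bias correction; one slot pair per parameter array."""

    def __init__(
        self,
        params: list[np.ndarray],
        lr: float = 1e-5,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        if lr <= 0:
            raise ValueError("learning rate must be positive")
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        lr_t = self.lr * np.sqrt(1 - self.b2**self.t) / (1 - self.b1**self.t)
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * np.square(g)
            p -= lr_t * m / (np.sqrt(v) + self.eps)
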