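"""Minimal convolutional-network engine on numpy.

Implements exactly the pieces the binary ablation classifier needs: strided
3x3 convolutions (im2col), ReLU, average/max pooling heads, a linear
classification layer, softmax cross-entropy, and SGD with momentum.  All
arithmetic is float32 and fully deterministic given the initialisation seed,
which the matched-pair score-symmetry guarantees rely on.

Layers follow a forward/backward protocol; a :class:`Sequential` chains
them.  Activations are NCHW.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv2d",
    "ReLU",
    "GlobalAvgPool",
    "BlockAvgPool",
    "SpatialMax",
    "Flatten",
    "Linear",
    "Sequential",
    "softmax",
    "softmax_cross_entropy",
    "SGDMomentum",
]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean cross-entropy loss and its gradient w.r.t. the logits."""
    n = logits.shape[0]
    probs = softmax(logits)
    loss = float(-np.log(np.clip(probs[np.arange(n), labels], 1e-12, None)).mean())
    grad = probs.copy()
    grad[np.arange(n), labels] -= 1.0
    return loss, grad / n


class Layer:
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def parameters(self) -> list[tuple[np.ndarray, np.ndarray]]:
        """(param, grad) pairs; grads are filled by backward."""
        return []


class Conv2d(Layer):
    """3x3-style strided convolution with zero padding, via im2col."""

    def __init__(self, cin: int, cout: int, k: int = 3, stride: int = 2,
                 pad: int = 1, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / (cin * k * k))  # He initialisation
        self.W = (rng.standard_normal((cout, cin * k * k)) * scale).astype(np.float32)
        self.b = np.zeros(cout, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.k, self.stride, self.pad = k, stride, pad
        self.cin, self.cout = cin, cout

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        k, s, p = self.k, self.stride, self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
        win = win[:, :, ::s, ::s]  # (n, c, ho, wo, k, k)
        ho, wo = win.shape[2], win.shape[3]
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * k * k)
        out = cols @ self.W.T + self.b
        if train:
            self._cache = (cols, x.shape, ho, wo)
        return out.reshape(n, ho, wo, self.cout).transpose(0, 3, 1, 2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        cols, xshape, ho, wo = self._cache
        n, c, h, w = xshape
        k, s, p = self.k, self.stride, self.pad
        dflat = dout.transpose(0, 2, 3, 1).reshape(-1, self.cout)
        self.dW[:] = dflat.T @ cols
        self.db[:] = dflat.sum(axis=0)
        dcols = (dflat @ self.W).reshape(n, ho, wo, c, k, k)
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=np.float32)
        for ki in range(k):
            for kj in range(k):
                dxp[:, :, ki : ki + s * ho : s, kj : kj + s * wo : s] += (
                    dcols[:, :, :, :, ki, kj].transpose(0, 3, 1, 2)
                )
        return dxp[:, :, p : p + h, p : p + w]

    def parameters(self):
        return [(self.W, self.dW), (self.b, self.db)]


class ReLU(Layer):
    def forward(self, x, train=False):
        if train:
            self._mask = x > 0
        return np.maximum(x, 0)

    def backward(self, dout):
        return dout * self._mask


class GlobalAvgPool(Layer):
    """Channel-wise mean over the whole spatial extent of the feature map."""

    def forward(self, x, train=False):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dout):
        n, c, h, w = self._shape
        return np.broadcast_to(dout[:, :, None, None], self._shape) / (h * w)


class BlockAvgPool(Layer):
    """Non-overlapping k x k average pooling (kernel = stride = k)."""

    def __init__(self, k: int):
        self.k = k

    def forward(self, x, train=False):
        n, c, h, w = x.shape
        k = self.k
        if h % k or w % k:
            raise ValueError(f"spatial size {h}x{w} not divisible by kernel {k}")
        self._shape = x.shape
        return x.reshape(n, c, h // k, k, w // k, k).mean(axis=(3, 5))

    def backward(self, dout):
        n, c, h, w = self._shape
        k = self.k
        up = np.repeat(np.repeat(dout, k, axis=2), k, axis=3)
        return up / (k * k)


class SpatialMax(Layer):
    """Maximum over the spatial extent, channel-wise."""

    def forward(self, x, train=False):
        n, c, h, w = x.shape
        flat = x.reshape(n, c, h * w)
        self._arg = flat.argmax(axis=2)
        self._shape = x.shape
        return flat.max(axis=2)

    def backward(self, dout):
        n, c, h, w = self._shape
        dx = np.zeros((n, c, h * w), dtype=np.float32)
        ni, ci = np.indices((n, c))
        dx[ni, ci, self._arg] = dout
        return dx.reshape(self._shape)


class Flatten(Layer):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Linear(Layer):
    def __init__(self, nin: int, nout: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(1.0 / nin)
        self.W = (rng.standard_normal((nin, nout)) * scale).astype(np.float32)
        self.b = np.zeros(nout, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x, train=False):
        if train:
            self._x = x
        return x @ self.W + self.b

    def backward(self, dout):
        self.dW[:] = self._x.T @ dout
        self.db[:] = dout.sum(axis=0)
        return dout @ self.W.T

    def parameters(self):
        return [(self.W, self.dW), (self.b, self.db)]


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dout):
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def parameters(self):
        return [p for layer in self.layers for p in layer.parameters()]


class SGDMomentum:
    """Plain SGD with momentum; every layer's weights are updated
    (the whole network is trainable, no frozen stages)."""

    def __init__(self, params, learning_rate: float, momentum: float = 0.9):
        self.params = params
        self.lr = learning_rate
        self.momentum = momentum
        self.velocity = [np.zeros_like(p) for p, _ in params]

    def step(self) -> None:
        for (p, g), v in zip(self.params, self.velocity):
            v *= self.momentum
            v -= self.lr * g
            p += v
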