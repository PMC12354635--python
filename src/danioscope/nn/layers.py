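"""Core layers: conv, pooling, dense, ReLU, dropout.

All activations are ``float64`` arrays in NHWC layout ``(batch, height,
width, channels)``.  Each layer owns its parameters and the gradients from
the most recent backward pass; ``trainable`` gates whether the optimiser
touches them (frozen layers still propagate gradients to earlier layers).
"""

from __future__ import annotations

import numpy as np


class Layer:
    """Base class; stateless layers only override forward/backward."""

    trainable: bool = True
    name: str = ""

    def params(self) -> dict[str, np.ndarray]:
        return {}

    def grads(self) -> dict[str, np.ndarray]:
        return {}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def he_normal(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


def glorot_uniform(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Conv2D(Layer):
    """Stride-1 'same' convolution with an odd square kernel.

    Implemented as im2col + one matrix product; the column tensor from the
    forward pass is cached for the weight gradient.
    """

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int = 3,
        rng: np.random.Generator | None = None,
        name: str = "conv",
    ) -> None:
        if kernel_size % 2 != 1 or kernel_size < 1:
            raise ValueError("kernel_size must be an odd positive integer")
        rng = rng or np.random.default_rng(0)
        self.kernel_size = kernel_size
        self.in_channels = in_channels
        self.out_channels = out_channels
        fan_in = kernel_size * kernel_size * in_channels
        self.weight = he_normal(rng, (kernel_size, kernel_size, in_channels, out_channels), fan_in)
        self.bias = np.zeros(out_channels)
        self.dweight = np.zeros_like(self.weight)
        self.dbias = np.zeros_like(self.bias)
        self.name = name
        self._cols: np.ndarray | None = None
        self._in_shape: tuple[int, ...] | None = None

    def params(self) -> dict[str, np.ndarray]:
        return {f"{self.name}/weight": self.weight, f"{self.name}/bias": self.bias}

    def grads(self) -> dict[str, np.ndarray]:
        return {f"{self.name}/weight": self.dweight, f"{self.name}/bias": self.dbias}

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        k = self.kernel_size
        p = k // 2
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        # (N, H, W, C, k, k) -> (N*H*W, k*k*C) with (ki, kj, c) ordering
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(1, 2))
        n, h, w, c = x.shape
        cols = win.transpose(0, 1, 2, 4, 5, 3).reshape(n * h * w, k * k * c)
        return cols

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if x.shape[3] != self.in_channels:
            raise ValueError(
                f"{self.name}: expected {self.in_channels} input channels, got {x.shape[3]}"
            )
        n, h, w, c = x.shape
        cols = self._im2col(x)
        wmat = self.weight.reshape(-1, self.out_channels)
        out = cols @ wmat + self.bias
        self._cols = cols
        self._in_shape = x.shape
        return out.reshape(n, h, w, self.out_channels)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        assert self._cols is not None and self._in_shape is not None
        n, h, w, c = self._in_shape
        k = self.kernel_size
        p = k // 2
        gflat = grad.reshape(n * h * w, self.out_channels)
        self.dweight = (self._cols.T @ gflat).reshape(self.weight.shape)
        self.dbias = gflat.sum(axis=0)
        dcols = (gflat @ self.weight.reshape(-1, self.out_channels).T).reshape(n, h, w, k, k, c)
        dxp = np.zeros((n, h + 2 * p, w + 2 * p, c))
        for i in range(k):
            for j in range(k):
                dxp[:, i : i + h, j : j + w, :] += dcols[:, :, :, i, j, :]
        return dxp[:, p : p + h, p : p + w, :]


class ReLU(Layer):
    def __init__(self) -> None:
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


class MaxPool2D(Layer):
    """2x2 max pooling with stride 2; spatial dims must be even."""

    def __init__(self) -> None:
        self._argmax: np.ndarray | None = None
        self._in_shape: tuple[int, ...] | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, h, w, c = x.shape
        if h % 2 or w % 2:
            raise ValueError("MaxPool2D requires even spatial dimensions")
        win = x.reshape(n, h // 2, 2, w // 2, 2, c).transpose(0, 1, 3, 5, 2, 4)
        win = win.reshape(n, h // 2, w // 2, c, 4)
        self._argmax = win.argmax(axis=-1)
        self._in_shape = x.shape
        return win.max(axis=-1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        assert self._argmax is not None and self._in_shape is not None
        n, h, w, c = self._in_shape
        onehot = np.eye(4)[self._argmax]  # (N, H/2, W/2, C, 4)
        dwin = grad[..., None] * onehot
        dwin = dwin.reshape(n, h // 2, w // 2, c, 2, 2).transpose(0, 1, 4, 2, 5, 3)
        return dwin.reshape(n, h, w, c)


class GlobalAveragePooling(Layer):
    """Mean over the spatial grid: (N, H, W, C) -> (N, C)."""

    def __init__(self) -> None:
        self._in_shape: tuple[int, ...] | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._in_shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, h, w, c = self._in_shape
        return np.broadcast_to(grad[:, None, None, :] / (h * w), (n, h, w, c)).copy()


class Dense(Layer):
    def __init__(
        self,
        in_features: int,
        out_features: int,
        rng: np.random.Generator | None = None,
        name: str = "dense",
    ) -> None:
        rng = rng or np.random.default_rng(0)
        self.weight = glorot_uniform(rng, (in_features, out_features), in_features, out_features)
        self.bias = np.zeros(out_features)
        self.dweight = np.zeros_like(self.weight)
        self.dbias = np.zeros_like(self.bias)
        self.name = name
        self._x: np.ndarray | None = None

    def params(self) -> dict[str, np.ndarray]:
        return {f"{self.name}/weight": self.weight, f"{self.name}/bias": self.bias}

    def grads(self) -> dict[str, np.ndarray]:
        return {f"{self.name}/weight": self.dweight, f"{self.name}/bias": self.dbias}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x = x
        return x @ self.weight + self.bias

    def backward(self, grad: np.ndarray) -> np.ndarray:
        assert self._x is not None
        self.dweight = self._x.T @ grad
        self.dbias = grad.sum(axis=0)
        return grad @ self.weight.T


class FeatureScale(Layer):
    """Multiply activations by a fixed constant (no parameters).

    Used to set the working magnitude of pooled descriptors entering the
    dense head; with adaptive-moment optimisers the achievable movement of
    the decision function at a given learning rate scales with the input
    magnitude, so this constant is part of the optimisation conditioning.
    """

    trainable = False

    def __init__(self, gain: float) -> None:
        if gain <= 0:
            raise ValueError("gain must be positive")
        self.gain = float(gain)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return x * self.gain

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self.gain


class Dropout(Layer):
    """Inverted dropout; identity at inference time."""

    def __init__(self, rate: float, rng: np.random.Generator | None = None) -> None:
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must lie in [0, 1)")
        self.rate = rate
        self.rng = rng or np.random.default_rng(0)
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return grad
        return grad * self._mask
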