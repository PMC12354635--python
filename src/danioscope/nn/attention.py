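"""Convolutional Block Attention Module (CBAM).

CBAM refines a convolutional feature map in two sequential stages:

1. *Channel attention*.  The map is summarised per channel by global average
   pooling and global max pooling; both descriptors pass through a shared
   two-layer bottleneck perceptron (hidden width ``channels //
   reduction_ratio``, floored to 1, ReLU), their outputs are summed, and a
   sigmoid yields one gate in (0, 1) per channel.
2. *Spatial attention*.  The channel-gated map is summarised per position by
   the channel-wise mean and channel-wise max; this 2-channel stack passes
   through a single-output ``spatial_kernel`` x ``spatial_kernel``
   convolution (zero-padded, shape preserving) and a sigmoid, yielding one
   gate in (0, 1) per spatial position.

The refined map is the input scaled elementwise by both broadcast gates, so
its shape always equals the input shape and its magnitude never exceeds the
input's.  For embryo images the intended effect is to up-weight channels and
locations carrying diagnostic colour foci (e.g. blood clots) and to suppress
background noise.

This module offers two surfaces: pure functions on a single ``(H, W, C)``
feature map given explicit parameters (used for oracle-style verification),
and the :class:`CBAM` layer with batched forward/backward for training.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .layers import Conv2D, Layer, he_normal


@dataclasses.dataclass(frozen=True)
class AttentionConfig:
    """CBAM hyperparameters (defaults from the originating CBAM design)."""

    reduction_ratio: int = 16
    spatial_kernel: int = 7

    def __post_init__(self) -> None:
        if self.reduction_ratio < 1:
            raise ValueError("reduction_ratio must be a positive integer")
        if self.spatial_kernel < 1 or self.spatial_kernel % 2 != 1:
            raise ValueError("spatial_kernel must be an odd positive integer")

    def hidden_units(self, channels: int) -> int:
        return max(1, channels // self.reduction_ratio)


@dataclasses.dataclass
class CBAMParams:
    """Learnable parameters: shared channel MLP + spatial convolution."""

    w1: np.ndarray  # (C, hidden)
    b1: np.ndarray  # (hidden,)
    w2: np.ndarray  # (hidden, C)
    b2: np.ndarray  # (C,)
    spatial_kernel: np.ndarray  # (k, k, 2, 1)
    spatial_bias: np.ndarray  # (1,)

    @classmethod
    def initialize(
        cls, channels: int, cfg: AttentionConfig, rng: np.random.Generator
    ) -> "CBAMParams":
        hidden = cfg.hidden_units(channels)
        k = cfg.spatial_kernel
        return cls(
            w1=he_normal(rng, (channels, hidden), channels),
            b1=np.zeros(hidden),
            w2=he_normal(rng, (hidden, channels), hidden),
            b2=np.zeros(channels),
            spatial_kernel=he_normal(rng, (k, k, 2, 1), k * k * 2),
            spatial_bias=np.zeros(1),
        )

    def validate(self, channels: int, cfg: AttentionConfig) -> None:
        hidden = cfg.hidden_units(channels)
        if self.w1.shape != (channels, hidden) or self.w2.shape != (hidden, channels):
            raise ValueError(
                f"channel MLP shapes {self.w1.shape}/{self.w2.shape} inconsistent "
                f"with {channels} channels and reduction_ratio {cfg.reduction_ratio}"
            )
        k = cfg.spatial_kernel
        if self.spatial_kernel.shape != (k, k, 2, 1):
            raise ValueError("spatial kernel shape inconsistent with spatial_kernel size")


def _sigmoid(x: np.ndarray) -> np.ndarray:
    # clamped just inside (0, 1): the gates' open-interval semantics survive
    # float saturation at extreme pre-activations
    return np.clip(0.5 * (1.0 + np.tanh(0.5 * x)), 1e-12, 1.0 - 1e-12)


def _check_feature_map(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 3 or min(x.shape) < 1:
        raise ValueError("feature map must be a 3-D (height, width, channels) tensor")
    if not np.all(np.isfinite(x)):
        raise ValueError("feature map must be finite")
    return x


def _channel_mlp(desc: np.ndarray, p: CBAMParams) -> np.ndarray:
    """Shared bottleneck perceptron applied to a (N, C) descriptor."""
    hidden = np.maximum(desc @ p.w1 + p.b1, 0.0)
    return hidden @ p.w2 + p.b2


def channel_attention(x: np.ndarray, cfg: AttentionConfig, params: CBAMParams) -> np.ndarray:
    """Per-channel gates: sigmoid(MLP(avg-pool) + MLP(max-pool)), each in (0,1)."""
    x = _check_feature_map(x)
    params.validate(x.shape[2], cfg)
    avg = x.mean(axis=(0, 1))[None, :]
    mx = x.max(axis=(0, 1))[None, :]
    return _sigmoid(_channel_mlp(avg, params) + _channel_mlp(mx, params))[0]


def spatial_attention(x: np.ndarray, cfg: AttentionConfig, params: CBAMParams) -> np.ndarray:
    """Per-position gates in (0,1) from the [channel-mean; channel-max] stack."""
    x = _check_feature_map(x)
    params.validate(x.shape[2], cfg)
    stack = np.stack([x.mean(axis=2), x.max(axis=2)], axis=-1)  # (H, W, 2)
    k = cfg.spatial_kernel
    p = k // 2
    padded = np.pad(stack, ((p, p), (p, p), (0, 0)))
    h, w = x.shape[:2]
    out = np.empty((h, w))
    kern = params.spatial_kernel[..., 0]  # (k, k, 2)
    for i in range(h):
        for j in range(w):
            out[i, j] = np.sum(padded[i : i + k, j : j + k, :] * kern)
    return _sigmoid(out + params.spatial_bias[0])


def cbam_refine(x: np.ndarray, cfg: AttentionConfig, params: CBAMParams) -> np.ndarray:
    """Apply channel then spatial attention; output shape equals input shape."""
    x = _check_feature_map(x)
    cw = channel_attention(x, cfg, params)
    x1 = x * cw[None, None, :]
    sw = spatial_attention(x1, cfg, params)
    return x1 * sw[:, :, None]


class CBAM(Layer):
    """Batched CBAM layer with backpropagation, for use inside a network.

    The spatial convolution is delegated to a :class:`Conv2D` sub-layer so
    its gradient machinery is shared with the backbone convolutions.
    """

    def __init__(
        self,
        channels: int,
        cfg: AttentionConfig | None = None,
        rng: np.random.Generator | None = None,
        name: str = "cbam",
    ) -> None:
        rng = rng or np.random.default_rng(0)
        self.cfg = cfg or AttentionConfig()
        self.channels = channels
        hidden = self.cfg.hidden_units(channels)
        self.w1 = he_normal(rng, (channels, hidden), channels)
        self.b1 = np.zeros(hidden)
        self.w2 = he_normal(rng, (hidden, channels), hidden)
        self.b2 = np.zeros(channels)
        self.spatial_conv = Conv2D(2, 1, self.cfg.spatial_kernel, rng=rng, name=f"{name}/spatial")
        self.dw1 = np.zeros_like(self.w1)
        self.db1 = np.zeros_like(self.b1)
        self.dw2 = np.zeros_like(self.w2)
        self.db2 = np.zeros_like(self.b2)
        self.name = name
        self._cache: dict[str, np.ndarray] | None = None

    # -- parameter plumbing -------------------------------------------------

    @property
    def trainable(self) -> bool:  # type: ignore[override]
        return self._trainable

    @trainable.setter
    def trainable(self, value: bool) -> None:
        self._trainable = value
        self.spatial_conv.trainable = value

    _trainable = True

    def params(self) -> dict[str, np.ndarray]:
        out = {
            f"{self.name}/w1": self.w1,
            f"{self.name}/b1": self.b1,
            f"{self.name}/w2": self.w2,
            f"{self.name}/b2": self.b2,
        }
        out.update(self.spatial_conv.params())
        return out

    def grads(self) -> dict[str, np.ndarray]:
        out = {
            f"{self.name}/w1": self.dw1,
            f"{self.name}/b1": self.db1,
            f"{self.name}/w2": self.dw2,
            f"{self.name}/b2": self.db2,
        }
        out.update(self.spatial_conv.grads())
        return out

    def export_params(self) -> CBAMParams:
        """View of the layer's parameters in functional form."""
        return CBAMParams(
            w1=self.w1,
            b1=self.b1,
            w2=self.w2,
            b2=self.b2,
            spatial_kernel=self.spatial_conv.weight,
            spatial_bias=self.spatial_conv.bias,
        )

    # -- forward / backward -------------------------------------------------

    def _mlp(self, desc: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        pre = desc @ self.w1 + self.b1
        hidden = np.maximum(pre, 0.0)
        return hidden, hidden @ self.w2 + self.b2

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if x.shape[3] != self.channels:
            raise ValueError(f"{self.name}: expected {self.channels} channels, got {x.shape[3]}")
        n, h, w, c = x.shape
        avg = x.mean(axis=(1, 2))
        mx = x.max(axis=(1, 2))
        h_avg, s_avg = self._mlp(avg)
        h_max, s_max = self._mlp(mx)
        cw = _sigmoid(s_avg + s_max)  # (N, C)
        y = x * cw[:, None, None, :]
        cmean = y.mean(axis=3)
        cmax = y.max(axis=3)
        stack = np.stack([cmean, cmax], axis=-1)  # (N, H, W, 2)
        u = self.spatial_conv.forward(stack, train=train)[..., 0]
        sw = _sigmoid(u)  # (N, H, W)
        out = y * sw[..., None]
        self._cache = {
            "x": x, "avg": avg, "mx": mx, "h_avg": h_avg, "h_max": h_max,
            "cw": cw, "y": y, "cmax_idx": y.argmax(axis=3), "sw": sw,
        }
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        c = self._cache
        assert c is not None
        x, cw, y, sw = c["x"], c["cw"], c["y"], c["sw"]
        n, h, w, nch = x.shape

        # spatial gate
        dsw = (grad * y).sum(axis=3)
        dy = grad * sw[..., None]
        du = dsw * sw * (1.0 - sw)
        dstack = self.spatial_conv.backward(du[..., None])
        dcmean, dcmax = dstack[..., 0], dstack[..., 1]
        dy += dcmean[..., None] / nch
        onehot = np.eye(nch)[c["cmax_idx"]]  # (N, H, W, C)
        dy += dcmax[..., None] * onehot

        # channel gate
        dcw = (dy * x).sum(axis=(1, 2))
        dx = dy * cw[:, None, None, :]
        ds = dcw * cw * (1.0 - cw)  # shared for both branches

        self.dw2 = c["h_avg"].T @ ds + c["h_max"].T @ ds
        self.db2 = 2.0 * ds.sum(axis=0)
        dh_avg = (ds @ self.w2.T) * (c["h_avg"] > 0)
        dh_max = (ds @ self.w2.T) * (c["h_max"] > 0)
        self.dw1 = c["avg"].T @ dh_avg + c["mx"].T @ dh_max
        self.db1 = (dh_avg + dh_max).sum(axis=0)
        davg = dh_avg @ self.w1.T
        dmx = dh_max @ self.w1.T

        dx += davg[:, None, None, :] / (h * w)
        # scatter max-pool gradient to the arg-max spatial position per (n, c)
        flat = x.reshape(n, h * w, nch)
        idx = flat.argmax(axis=1)  # (N, C)
        dflat = np.zeros_like(flat)
        np.put_along_axis(dflat, idx[:, None, :], dmx[:, None, :], axis=1)
        dx += dflat.reshape(n, h, w, nch)
        return dx
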