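"""Layers with forward/backward passes on float32 NCHW arrays."""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Layer",
    "Conv2D",
    "ReLU",
    "MaxPool2",
    "GlobalAveragePool",
    "GlobalMaxPool",
    "BatchNorm1D",
    "Dropout",
    "Dense",
    "softmax",
    "softmax_cross_entropy",
]


class Layer:
    """Base layer. Parameters live in ``params``; gradients in ``grads``."""

    trainable: bool = True

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool = False, rng=None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    @property
    def n_params(self) -> int:
        return sum(int(p.size) for p in self.params.values())


def _im2col(x: np.ndarray) -> np.ndarray:
    """(N, C, H+2, W+2) padded input -> (N*H*W, C*9) patch matrix."""
    # windows: (N, C, H, W, 3, 3)
    windows = sliding_window_view(x, (3, 3), axis=(2, 3))
    n, c, h, w = windows.shape[:4]
    # -> (N, H, W, C, 3, 3) -> (N*H*W, C*9)
    cols = windows.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * 9)
    return np.ascontiguousarray(cols)


class Conv2D(Layer):
    """3x3 convolution, stride 1, one-pixel zero padding (shape-preserving)."""

    def __init__(self, in_channels: int, out_channels: int, rng: np.random.Generator):
        super().__init__()
        self.in_channels = in_channels
        self.out_channels = out_channels
        fan_in = in_channels * 9
        # He initialization suits the ReLU that follows every convolution.
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(out_channels, fan_in))
        self.params = {
            "W": w.astype(np.float32),
            "b": np.zeros(out_channels, dtype=np.float32),
        }
        self._cols: np.ndarray | None = None
        self._in_shape: tuple[int, ...] | None = None
        self.compute_input_grad = True

    def forward(self, x: np.ndarray, train: bool = False, rng=None) -> np.ndarray:
        n, c, h, w = x.shape
        padded = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        cols = _im2col(padded)
        if train:
            self._cols = cols
            self._in_shape = x.shape
        out = cols @ self.params["W"].T + self.params["b"]
        return out.reshape(n, h, w, self.out_channels).transpose(0, 3, 1, 2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, f, h, w = dout.shape
        dout_mat = dout.transpose(0, 2, 3, 1).reshape(n * h * w, f)
        if self.trainable:
            self.grads["W"] = (dout_mat.T @ self._cols).astype(np.float32)
            self.grads["b"] = dout_mat.sum(axis=0).astype(np.float32)
        self._cols = None
        if not self.compute_input_grad:
            return np.zeros(self._in_shape, dtype=np.float32)
        # dX is the correlation of dout with spatially flipped kernels.
        w_spat = self.params["W"].reshape(f, self.in_channels, 3, 3)
        w_flip = w_spat[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)  # (Cin, F, 3, 3)
        w_flip = w_flip.reshape(self.in_channels, f * 9)
        dpad = np.pad(dout, ((0, 0), (0, 0), (1, 1), (1, 1)))
        dcols = _im2col(dpad)  # (N*H*W, F*9)
        dx = dcols @ w_flip.T
        return (
            dx.reshape(n, h, w, self.in_channels)
            .transpose(0, 3, 1, 2)
            .astype(np.float32)
        )


class ReLU(Layer):
    def __init__(self) -> None:
        super().__init__()
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = False, rng=None) -> np.ndarray:
        out = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class MaxPool2(Layer):
    """2x2 max pooling with stride 2; input spatial dims must be even."""

    def __init__(self) -> None:
        super().__init__()
        self._argmax: np.ndarray | None = None
        self._in_shape: tuple[int, ...] | None = None

    def forward(self, x: np.ndarray, train: bool = False, rng=None) -> np.ndarray:
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"pooling input dims must be even, got {h}x{w}")
        tiles = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        tiles = tiles.reshape(n, c, h // 2, w // 2, 4)
        if train:
            self._argmax = tiles.argmax(axis=-1)
            self._in_shape = x.shape
            return np.take_along_axis(
                tiles, self._argmax[..., None], axis=-1
            ).squeeze(-1)
        return tiles.max(axis=-1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._in_shape
        grid = np.zeros((n, c, h // 2, w // 2, 4), dtype=np.float32)
        np.put_along_axis(grid, self._argmax[..., None], dout[..., None], axis=-1)
        grid = grid.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return grid.reshape(n, c, h, w)


class GlobalAveragePool(Layer):
    """(N, C, H, W) -> (N, C) by per-channel spatial mean ("energy")."""

    def __init__(self) -> None:
        super().__init__()
        self._spatial: tuple[int, int] | None = None

    def forward(self, x: np.ndarray, train: bool = False, rng=None) -> np.ndarray:
        self._spatial = x.shape[2:]
        return x.mean(axis=(2, 3))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        h, w = self._spatial
        return np.broadcast_to(
            dout[:, :, None, None] / (h * w), dout.shape + (h, w)
        ).astype(np.float32)


class GlobalMaxPool(Layer):
    """(N, C, H, W) -> (N, C) by per-channel spatial maximum."""

    def __init__(self) -> None:
        super().__init__()
        self._argmax: np.ndarray | None = None
        self._spatial: tuple[int, int] | None = None

    def forward(self, x: np.ndarray, train: bool = False, rng=None) -> np.ndarray:
        n, c, h, w = x.shape
        flat = x.reshape(n, c, h * w)
        self._spatial = (h, w)
        if train:
            self._argmax = flat.argmax(axis=-1)
            return np.take_along_axis(
                flat, self._argmax[..., None], axis=-1
            ).squeeze(-1)
        return flat.max(axis=-1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c = dout.shape
        h, w = self._spatial
        grid = np.zeros((n, c, h * w), dtype=np.float32)
        np.put_along_axis(grid, self._argmax[..., None], dout[..., None], axis=-1)
        return grid.reshape(n, c, h, w)


class BatchNorm1D(Layer):
    """Batch normalization over a (N, C) feature vector.

    Training uses batch statistics and updates exponential running averages
    used at evaluation time.
    """

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        super().__init__()
        self.momentum = momentum
        self.eps = eps
        self.params = {
            "gamma": np.ones(channels, dtype=np.float32),
            "beta": np.zeros(channels, dtype=np.float32),
        }
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self._cache = None

    def forward(self, x: np.ndarray, train: bool = False, rng=None) -> np.ndarray:
        if train:
            mean = x.mean(axis=0)
            var = x.var(axis=0)
            self.running_mean = (
                self.momentum * self.running_mean + (1 - self.momentum) * mean
            ).astype(np.float32)
            self.running_var = (
                self.momentum * self.running_var + (1 - self.momentum) * var
            ).astype(np.float32)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv_std
        if train:
            self._cache = (xhat, inv_std)
        return self.params["gamma"] * xhat + self.params["beta"]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv_std = self._cache
        n = dout.shape[0]
        self.grads["gamma"] = (dout * xhat).sum(axis=0).astype(np.float32)
        self.grads["beta"] = dout.sum(axis=0).astype(np.float32)
        dxhat = dout * self.params["gamma"]
        dx = (
            inv_std
            / n
            * (n * dxhat - dxhat.sum(axis=0) - xhat * (dxhat * xhat).sum(axis=0))
        )
        return dx.astype(np.float32)

    def state(self) -> dict[str, np.ndarray]:
        return {"running_mean": self.running_mean, "running_var": self.running_var}

    def set_state(self, state: dict[str, np.ndarray]) -> None:
        self.running_mean = state["running_mean"].astype(np.float32).copy()
        self.running_var = state["running_var"].astype(np.float32).copy()


class Dropout(Layer):
    """Inverted dropout; identity at evaluation time."""

    def __init__(self, rate: float):
        super().__init__()
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = False, rng=None) -> np.ndarray:
        if not train or self.rate == 0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("training-mode dropout needs an RNG")
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dout
        return dout * self._mask


class Dense(Layer):
    """Fully connected layer producing class logits."""

    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        super().__init__()
        limit = np.sqrt(6.0 / (in_features + out_features))  # Glorot uniform
        self.params = {
            "W": rng.uniform(-limit, limit, size=(in_features, out_features)).astype(
                np.float32
            ),
            "b": np.zeros(out_features, dtype=np.float32),
        }
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = False, rng=None) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.grads["W"] = (self._x.T @ dout).astype(np.float32)
        self.grads["b"] = dout.sum(axis=0).astype(np.float32)
        return (dout @ self.params["W"].T).astype(np.float32)


def softmax(logits: np.ndarray) -> np.ndarray:
    """Row-wise softmax, numerically stabilized."""
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(
    logits: np.ndarray, labels: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean categorical cross-entropy and its gradient w.r.t. the logits."""
    probs = softmax(logits)
    n = logits.shape[0]
    eps = np.finfo(np.float32).tiny
    loss = -np.log(probs[np.arange(n), labels] + eps).mean()
    grad = probs.copy()
    grad[np.arange(n), labels] -= 1.0
    return float(loss), (grad / n).astype(np.float32)
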