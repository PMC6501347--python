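"""Minimal NumPy neural-network kernel used by the surrogate model.

Implements exactly the layer set the surrogate architecture needs —
2-D convolution (stride 1, size-preserving padding), ReLU, 2x2 average
pooling, flatten, inverted dropout and dense layers — plus the Adagrad
optimizer and the mean-absolute-percentage-error loss.  Convolutions are
evaluated through an im2col lowering onto BLAS matrix products; forward and
backward passes are exact (the backward input gradient of a same-padded
stride-1 convolution is a same-padded convolution with the spatially
flipped, channel-transposed kernel).

Everything is deterministic given the generator passed to ``init`` /
``train`` — there is no hidden global random state.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


def _glorot_uniform(rng: np.random.Generator, shape, fan_in: int, fan_out: int):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(DTYPE)


class Layer:
    """Base layer; stateless layers keep the default no-param behaviour."""

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def parameters(self) -> list[np.ndarray]:
        return []

    def gradients(self) -> list[np.ndarray]:
        return []


_SMALL_PATCH = 64  # below this ci*k*k, a transposed im2col beats shifted GEMMs


def _im2col_t(xp: np.ndarray, h: int, wd: int, k: int) -> np.ndarray:
    """Transposed im2col: rows are contiguous shifted copies, (k*k*ci, B*h*wd)."""
    b, _, _, ci = xp.shape
    cols = np.empty((k * k * ci, b * h * wd), dtype=xp.dtype)
    row = 0
    for a in range(k):
        for c in range(k):
            s = xp[:, a : a + h, c : c + wd, :]
            for ch in range(ci):
                cols[row] = s[..., ch].reshape(-1)
                row += 1
    return cols


def _conv_same(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Same-padded stride-1 correlation of (B, H, W, Ci) with (k, k, Ci, Co).

    For wide inputs the convolution is evaluated as k*k shifted GEMMs — the
    classic im2col lowering materializes a k*k-fold copy of the input, which
    dominates runtime at this problem size.  For few input channels a
    transposed im2col (contiguous row copies, one fat GEMM) wins instead.
    """
    b, h, wd, ci = x.shape
    k, co = w.shape[0], w.shape[3]
    p = k // 2
    xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
    if ci * k * k <= _SMALL_PATCH:
        cols = _im2col_t(xp, h, wd, k)
        # kernel rows must match (a, c, ci) ordering of the im2col rows
        wmat = w.reshape(k * k * ci, co)
        return (cols.T @ wmat).reshape(b, h, wd, co)
    acc = np.zeros((b * h * wd, co), dtype=x.dtype)
    for a in range(k):
        for c in range(k):
            s = np.ascontiguousarray(xp[:, a : a + h, c : c + wd, :])
            acc += s.reshape(-1, ci) @ w[a, c]
    return acc.reshape(b, h, wd, co)


class Conv2D(Layer):
    """Same-padded stride-1 convolution, NHWC layout, kernel (kh, kw, ci, co)."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator, needs_input_grad: bool = True):
        k = kernel_size
        if k % 2 != 1:
            raise ValueError("kernel size must be odd for symmetric same padding")
        self.k = k
        self.needs_input_grad = needs_input_grad
        self.ci = in_channels
        self.co = out_channels
        fan_in = k * k * in_channels
        fan_out = k * k * out_channels
        self.w = _glorot_uniform(rng, (k, k, in_channels, out_channels), fan_in, fan_out)
        self.b = np.zeros(out_channels, dtype=DTYPE)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)
        self._xpad: np.ndarray | None = None
        self._shape: tuple | None = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        out = _conv_same(x, self.w) + self.b
        if train:
            p = self.k // 2
            self._xpad = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
            self._shape = x.shape
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        b, h, w, _ = self._shape
        gflat = grad.reshape(b * h * w, self.co)
        self.gb = gflat.sum(axis=0)
        if self.ci * self.k * self.k <= _SMALL_PATCH:
            cols = _im2col_t(self._xpad, h, w, self.k)
            self.gw = (cols @ gflat).reshape(self.w.shape)
        else:
            gw = np.empty_like(self.w)
            for a in range(self.k):
                for c in range(self.k):
                    s = np.ascontiguousarray(self._xpad[:, a : a + h, c : c + w, :])
                    gw[a, c] = s.reshape(-1, self.ci).T @ gflat
            self.gw = gw
        self._xpad = None
        if not self.needs_input_grad:  # first layer: input gradient unused
            return grad
        # input gradient: same-padded conv with flipped, transposed kernel
        w_back = np.ascontiguousarray(self.w[::-1, ::-1].transpose(0, 1, 3, 2))
        return _conv_same(grad, w_back)

    def parameters(self):
        return [self.w, self.b]

    def gradients(self):
        return [self.gw, self.gb]


class ReLU(Layer):
    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class AvgPool2(Layer):
    """2x2 average pooling with stride 2; odd trailing rows/cols dropped."""

    def forward(self, x, train):
        b, h, w, c = x.shape
        h2, w2 = h // 2, w // 2
        self._in_shape = x.shape
        xc = x[:, : 2 * h2, : 2 * w2, :]
        return xc.reshape(b, h2, 2, w2, 2, c).mean(axis=(2, 4))

    def backward(self, grad):
        b, h, w, c = self._in_shape
        h2, w2 = h // 2, w // 2
        gx = np.zeros(self._in_shape, dtype=grad.dtype)
        up = np.repeat(np.repeat(grad, 2, axis=1), 2, axis=2) * 0.25
        gx[:, : 2 * h2, : 2 * w2, :] = up
        return gx


class Flatten(Layer):
    def forward(self, x, train):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng: np.random.Generator | None = None

    def forward(self, x, train):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, grad):
        if self._mask is None:
            return grad
        return grad * self._mask


class Dense(Layer):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        self.w = _glorot_uniform(rng, (in_features, out_features), in_features, out_features)
        self.b = np.zeros(out_features, dtype=DTYPE)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)

    def forward(self, x, train):
        self._x = x if train else None
        return x @ self.w + self.b

    def backward(self, grad):
        self.gw = self._x.T @ grad
        self.gb = grad.sum(axis=0)
        self._x = None
        return grad @ self.w.T

    def parameters(self):
        return [self.w, self.b]

    def gradients(self):
        return [self.gw, self.gb]


class Sequential:
    """Plain layer stack with explicit train/inference modes."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, grad: np.ndarray) -> None:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)

    def set_dropout_rng(self, rng: np.random.Generator) -> None:
        for layer in self.layers:
            if isinstance(layer, Dropout):
                layer.rng = rng

    def parameters(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.parameters()]

    def gradients(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.gradients()]

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.parameters()))


class Adagrad:
    """Per-parameter adaptive gradient accumulation."""

    def __init__(self, params: list[np.ndarray], lr: float, eps: float = 1e-7):
        self.params = params
        self.lr = lr
        self.eps = eps
        self.acc = [np.zeros_like(p) for p in params]

    def step(self, grads: list[np.ndarray]) -> None:
        for p, g, a in zip(self.params, grads, self.acc):
            a += g * g
            p -= self.lr * g / (np.sqrt(a) + self.eps)


def mape(true: np.ndarray, predicted: np.ndarray) -> float:
    """Mean absolute percentage error, relative to the TRUE values.

    ``100 * mean over samples of mean over outputs of |pred - true| / |true|``.
    """
    true = np.asarray(true, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if true.shape != predicted.shape:
        raise ValueError(f"shape mismatch {true.shape} vs {predicted.shape}")
    if np.any(true == 0):
        raise ValueError("true values must be non-zero for MAPE")
    return float(100.0 * np.mean(np.abs(predicted - true) / np.abs(true)))


def mape_loss_and_grad(true: np.ndarray, predicted: np.ndarray):
    """Loss value and gradient with respect to the predictions."""
    diff = predicted - true
    denom = np.abs(true)
    loss = float(100.0 * np.mean(np.abs(diff) / denom))
    grad = (100.0 / diff.size) * np.sign(diff) / denom
    return loss, grad.astype(predicted.dtype)
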