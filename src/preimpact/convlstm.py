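"""Conv+LSTM sequence classifier over raw 9-channel sensor windows.

Topology (fixed): three convolutional blocks — 1-D convolution (same
padding), batch normalization, ReLU, max pooling — followed by two stacked
LSTM layers with dropout, a fully connected layer and a softmax over
{fall, adl}.  The convolutional front end extracts short-term local patterns
from the raw window; the recurrent layers model the temporal evolution of
those patterns across the window.

The network is implemented directly on numpy with hand-written
backpropagation and Adam updates, which keeps training bit-reproducible
under a fixed seed on a single thread.  Layer gradients are validated by
finite differences in the test suite.  Block sizes are configurable; the
package defaults (filters 16/32/64, kernel 5, pool 2, hidden 64) are sized
for CPU training on a few thousand windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import TrainingError, UsageError


@dataclass
class ConvLSTMSpec:
    """Sizes of the fixed three-conv-block / two-LSTM topology."""

    input_width: int = 50
    input_channels: int = 9
    conv_filters: tuple[int, int, int] = (16, 32, 64)
    kernel: int = 5
    pool: int = 2
    lstm_hidden: int = 64
    dropout: float = 0.5
    n_classes: int = 2

    def __post_init__(self) -> None:
        if len(self.conv_filters) != 3:
            raise UsageError("exactly three convolutional blocks are required")
        if self.kernel % 2 != 1 or self.kernel < 1:
            raise UsageError("kernel must be an odd positive integer")
        if not 0.0 <= self.dropout < 1.0:
            raise UsageError("dropout must be in [0, 1)")
        t = self.input_width
        for _ in range(3):
            t = t // self.pool
        if t < 1:
            raise UsageError(
                f"pooling (size {self.pool} x3) collapses the temporal axis of a "
                f"{self.input_width}-frame window below 1")
        self.output_width = t


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


class _Param:
    __slots__ = ("value", "grad", "m", "v")

    def __init__(self, value: np.ndarray) -> None:
        self.value = value
        self.grad = np.zeros_like(value)
        self.m = np.zeros_like(value)
        self.v = np.zeros_like(value)


class _Conv1D:
    """Same-padding 1-D convolution over (N, T, C_in) -> (N, T, C_out)."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        scale = np.sqrt(6.0 / (kernel * c_in + c_out))
        self.k = kernel
        self.W = _Param(rng.uniform(-scale, scale, size=(kernel * c_in, c_out)))
        self.b = _Param(np.zeros(c_out))

    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, t, c = x.shape
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (p, p), (0, 0)))
        cols = np.lib.stride_tricks.sliding_window_view(xp, self.k, axis=1)
        # cols: (n, t, c, k) -> (n, t, k, c)
        cols = np.ascontiguousarray(cols.transpose(0, 1, 3, 2)).reshape(n * t, self.k * c)
        self._cache = (cols, (n, t, c))
        y = cols @ self.W.value + self.b.value
        return y.reshape(n, t, -1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        cols, (n, t, c) = self._cache
        dyf = dy.reshape(n * t, -1)
        self.W.grad += cols.T @ dyf
        self.b.grad += dyf.sum(axis=0)
        dcols = (dyf @ self.W.value.T).reshape(n, t, self.k, c)
        p = self.k // 2
        dxp = np.zeros((n, t + 2 * p, c))
        for i in range(self.k):
            dxp[:, i:i + t] += dcols[:, :, i]
        return dxp[:, p:p + t]


class _BatchNorm:
    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = _Param(np.ones(c))
        self.beta = _Param(np.zeros(c))
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(c)
        self.running_var = np.ones(c)

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        shape = x.shape
        xf = x.reshape(-1, shape[-1])
        if train:
            mean = xf.mean(axis=0)
            var = xf.var(axis=0)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        std = np.sqrt(var + self.eps)
        xhat = (xf - mean) / std
        self._cache = (xhat, std, shape, train)
        return (xhat * self.gamma.value + self.beta.value).reshape(shape)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, std, shape, train = self._cache
        dyf = dy.reshape(-1, shape[-1])
        self.gamma.grad += (dyf * xhat).sum(axis=0)
        self.beta.grad += dyf.sum(axis=0)
        if not train:
            return (dyf * self.gamma.value / std).reshape(shape)
        m = dyf.shape[0]
        dxhat = dyf * self.gamma.value
        dx = (dxhat - dxhat.mean(axis=0) - xhat * (dxhat * xhat).mean(axis=0)) / std
        return dx.reshape(shape)


class _ReLU:
    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class _MaxPool:
    def __init__(self, pool: int):
        self.p = pool

    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, t, c = x.shape
        t_out = t // self.p
        xt = x[:, :t_out * self.p].reshape(n, t_out, self.p, c)
        self._arg = xt.argmax(axis=2)
        self._shape = (n, t, c, t_out)
        return np.take_along_axis(xt, self._arg[:, :, None, :], axis=2)[:, :, 0, :]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, t, c, t_out = self._shape
        dxt = np.zeros((n, t_out, self.p, c))
        np.put_along_axis(dxt, self._arg[:, :, None, :], dy[:, :, None, :], axis=2)
        dx = np.zeros((n, t, c))
        dx[:, :t_out * self.p] = dxt.reshape(n, t_out * self.p, c)
        return dx


class _LSTM:
    """Single LSTM layer returning the full hidden sequence (N, T, H)."""

    def __init__(self, c_in: int, hidden: int, rng: np.random.Generator):
        s_x = np.sqrt(6.0 / (c_in + 4 * hidden))
        s_h = np.sqrt(6.0 / (hidden + 4 * hidden))
        self.h = hidden
        self.Wx = _Param(rng.uniform(-s_x, s_x, size=(c_in, 4 * hidden)))
        self.Wh = _Param(rng.uniform(-s_h, s_h, size=(hidden, 4 * hidden)))
        b = np.zeros(4 * hidden)
        b[hidden:2 * hidden] = 1.0  # forget-gate bias
        self.b = _Param(b)

    def params(self):
        return [self.Wx, self.Wh, self.b]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, t, _ = x.shape
        hd = self.h
        h = np.zeros((n, hd))
        c = np.zeros((n, hd))
        hs = np.empty((n, t, hd))
        caches = []
        for step in range(t):
            z = x[:, step] @ self.Wx.value + h @ self.Wh.value + self.b.value
            i = _sigmoid(z[:, :hd])
            f = _sigmoid(z[:, hd:2 * hd])
            g = np.tanh(z[:, 2 * hd:3 * hd])
            o = _sigmoid(z[:, 3 * hd:])
            c_new = f * c + i * g
            tc = np.tanh(c_new)
            h_new = o * tc
            caches.append((x[:, step], h, c, i, f, g, o, tc))
            h, c = h_new, c_new
            hs[:, step] = h
        self._caches = caches
        return hs

    def backward(self, dhs: np.ndarray) -> np.ndarray:
        n, t, hd = dhs.shape
        dx = np.empty((n, t, self.Wx.value.shape[0]))
        dh_next = np.zeros((n, hd))
        dc_next = np.zeros((n, hd))
        for step in range(t - 1, -1, -1):
            x_t, h_prev, c_prev, i, f, g, o, tc = self._caches[step]
            dh = dhs[:, step] + dh_next
            do = dh * tc
            dc = dh * o * (1 - tc ** 2) + dc_next
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate([di * i * (1 - i), df * f * (1 - f),
                                 dg * (1 - g ** 2), do * o * (1 - o)], axis=1)
            self.Wx.grad += x_t.T @ dz
            self.Wh.grad += h_prev.T @ dz
            self.b.grad += dz.sum(axis=0)
            dx[:, step] = dz @ self.Wx.value.T
            dh_next = dz @ self.Wh.value.T
            dc_next = dc * f
        return dx


class _Dropout:
    def __init__(self, rate: float):
        self.rate = rate
        self.rng: np.random.Generator | None = None

    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy if self._mask is None else dy * self._mask


class _Dense:
    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        scale = np.sqrt(6.0 / (c_in + c_out))
        self.W = _Param(rng.uniform(-scale, scale, size=(c_in, c_out)))
        self.b = _Param(np.zeros(c_out))

    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.W.grad += self._x.T @ dy
        self.b.grad += dy.sum(axis=0)
        return dy @ self.W.value.T


class ConvLSTMNet:
    """The assembled network.  Use :func:`build_convlstm` to construct."""

    def __init__(self, spec: ConvLSTMSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        f1, f2, f3 = spec.conv_filters
        self.blocks = []
        c_in = spec.input_channels
        for c_out in (f1, f2, f3):
            self.blocks += [_Conv1D(c_in, c_out, spec.kernel, rng),
                            _BatchNorm(c_out), _ReLU(), _MaxPool(spec.pool)]
            c_in = c_out
        self.lstm1 = _LSTM(f3, spec.lstm_hidden, rng)
        self.drop1 = _Dropout(spec.dropout)
        self.lstm2 = _LSTM(spec.lstm_hidden, spec.lstm_hidden, rng)
        self.drop2 = _Dropout(spec.dropout)
        self.head = _Dense(spec.lstm_hidden, spec.n_classes, rng)
        self._layers = self.blocks + [self.lstm1, self.drop1, self.lstm2,
                                      self.drop2, self.head]

    def params(self) -> list[_Param]:
        return [p for layer in self._layers for p in layer.params()]

    def _check_input(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if x.ndim == 2:
            x = x[None]
        if x.ndim != 3 or x.shape[1:] != (self.spec.input_width, self.spec.input_channels):
            raise UsageError(
                f"input must have shape (n, {self.spec.input_width}, "
                f"{self.spec.input_channels}); got {x.shape}")
        return x

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Class probabilities, shape (n, n_classes)."""
        h = self._check_input(x)
        for layer in self.blocks:
            h = layer.forward(h, train)
        h = self.drop1.forward(self.lstm1.forward(h, train), train)
        h = self.drop2.forward(self.lstm2.forward(h, train), train)
        self._t_out = h.shape[1]
        logits = self.head.forward(h[:, -1], train)
        logits = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(logits)
        return e / e.sum(axis=1, keepdims=True)

    def backward_from_probs(self, probs: np.ndarray, y: np.ndarray,
                            sample_weight: np.ndarray) -> None:
        """Accumulate gradients of the weighted cross-entropy at the last forward pass."""
        n = len(y)
        dlogits = probs.copy()
        dlogits[np.arange(n), y] -= 1.0
        dlogits *= sample_weight[:, None] / sample_weight.sum()
        dh_last = self.head.backward(dlogits)
        dh2 = np.zeros((n, self._t_out, self.spec.lstm_hidden))
        dh2[:, -1] = dh_last
        dh = self.lstm1.backward(self.drop1.backward(
            self.lstm2.backward(self.drop2.backward(dh2))))
        for layer in reversed(self.blocks):
            dh = layer.backward(dh)

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[:] = 0.0


def build_convlstm(spec: ConvLSTMSpec | None = None, seed: int = 0) -> ConvLSTMNet:
    """Construct the network with seeded initialization (validates the spec)."""
    return ConvLSTMNet(spec or ConvLSTMSpec(), seed=seed)


def _adam_step(params: list[_Param], lr: float, t: int,
               beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8) -> None:
    for p in params:
        p.m = beta1 * p.m + (1 - beta1) * p.grad
        p.v = beta2 * p.v + (1 - beta2) * p.grad ** 2
        mhat = p.m / (1 - beta1 ** t)
        vhat = p.v / (1 - beta2 ** t)
        p.value -= lr * mhat / (np.sqrt(vhat) + eps)


def train_convlstm(windows: np.ndarray, labels: np.ndarray,
                   spec: ConvLSTMSpec | None = None, epochs: int = 10,
                   lr: float = 1e-3, batch_size: int = 32, seed: int = 0,
                   class_weight: str | None = "balanced"
                   ) -> tuple[ConvLSTMNet, list[float]]:
    """Train by minimizing (class-weighted) cross-entropy with Adam.

    ``windows`` is (n, 50, 9) raw sensor data, ``labels`` an integer vector
    (1 = fall, 0 = adl).  All randomness — initialization, batch shuffling,
    dropout — derives from ``seed``, so the returned loss history is
    reproducible run-to-run.  Raises :class:`TrainingError` if the loss
    becomes non-finite.
    """
    X = np.asarray(windows, dtype=float)
    y = np.asarray(labels, dtype=int)
    if X.ndim != 3 or len(X) != len(y):
        raise UsageError("windows must be (n, width, channels) aligned with labels")
    classes = np.unique(y)
    if len(classes) < 2:
        raise UsageError("training requires both fall and ADL windows")
    spec = spec or ConvLSTMSpec(input_width=X.shape[1], input_channels=X.shape[2])
    net = build_convlstm(spec, seed=seed)
    rng = np.random.default_rng(seed + 1)
    net.drop1.rng = np.random.default_rng(seed + 2)
    net.drop2.rng = np.random.default_rng(seed + 3)
    if class_weight == "balanced":
        counts = np.bincount(y, minlength=spec.n_classes)
        w_class = len(y) / (len(classes) * np.maximum(counts, 1))
    else:
        w_class = np.ones(spec.n_classes)
    sw = w_class[y]
    history: list[float] = []
    step = 0
    n = len(y)
    for epoch in range(epochs):
        order = rng.permutation(n)
        losses = []
        for lo in range(0, n, batch_size):
            idx = order[lo:lo + batch_size]
            if len(idx) < 2:
                continue  # batch norm needs >= 2 samples
            net.zero_grad()
            probs = net.forward(X[idx], train=True)
            p_true = np.clip(probs[np.arange(len(idx)), y[idx]], 1e-12, None)
            loss = float(-(sw[idx] * np.log(p_true)).sum() / sw[idx].sum())
            if not np.isfinite(loss):
                raise TrainingError(f"non-finite loss at epoch {epoch}")
            net.backward_from_probs(probs, y[idx], sw[idx])
            step += 1
            _adam_step(net.params(), lr, step)
            losses.append(loss)
        history.append(float(np.mean(losses)))
    return net, history
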