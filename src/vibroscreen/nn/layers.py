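"""Minimal NumPy neural-network layers with explicit backward passes.

Just enough machinery for the desk-scale CNN–BiLSTM risk scorer:
2-D convolution (im2col), ReLU, global average pooling, fully connected
layers, a residual block, an LSTM unrolled by hand, and Adam.  Each
layer caches what its backward pass needs; parameter gradients
accumulate into ``grads`` aligned with ``params``.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Conv2d", "ReLU", "GlobalAvgPool", "Linear", "ResidualBlock",
           "LSTMCell", "lstm_forward", "lstm_backward", "Adam",
           "sigmoid"]


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class Layer:
    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def zero_grad(self):
        for k in self.params:
            self.grads[k] = np.zeros_like(self.params[k])


class Conv2d(Layer):
    """3×3 (by default) convolution with zero padding, via im2col."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int = 3, stride: int = 1,
                 padding: int = 1, rng: np.random.Generator | None = None):
        super().__init__()
        self.in_ch, self.out_ch = in_ch, out_ch
        self.k, self.stride, self.pad = kernel, stride, padding
        rng = rng or np.random.default_rng(0)
        fan_in = in_ch * kernel * kernel
        self.params["W"] = rng.normal(0, np.sqrt(2.0 / fan_in),
                                      size=(out_ch, in_ch, kernel, kernel))
        self.params["b"] = np.zeros(out_ch)
        self.zero_grad()

    def _cols(self, x: np.ndarray) -> np.ndarray:
        # x: (N, C, H, W) -> (N, Ho, Wo, C*k*k)
        xp = np.pad(x, ((0, 0), (0, 0), (self.pad,) * 2, (self.pad,) * 2))
        win = np.lib.stride_tricks.sliding_window_view(xp, (self.k, self.k),
                                                       axis=(2, 3))
        win = win[:, :, ::self.stride, ::self.stride]  # (N, C, Ho, Wo, k, k)
        n, c, ho, wo = win.shape[:4]
        return win.transpose(0, 2, 3, 1, 4, 5).reshape(n, ho, wo, c * self.k * self.k)

    def forward(self, x: np.ndarray) -> np.ndarray:
        if min(x.shape[2], x.shape[3]) + 2 * self.pad < self.k:
            raise ValueError(
                f"input {x.shape[2]}×{x.shape[3]} is smaller than the "
                f"{self.k}×{self.k} kernel even after padding"
            )
        self._x_shape = x.shape
        self._cols_cache = self._cols(x)
        w = self.params["W"].reshape(self.out_ch, -1)
        out = self._cols_cache @ w.T + self.params["b"]
        return out.transpose(0, 3, 1, 2)  # (N, O, Ho, Wo)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, _o, ho, wo = dout.shape
        d = dout.transpose(0, 2, 3, 1).reshape(-1, self.out_ch)  # (N*Ho*Wo, O)
        cols = self._cols_cache.reshape(-1, self._cols_cache.shape[-1])
        self.grads["W"] += (d.T @ cols).reshape(self.params["W"].shape)
        self.grads["b"] += d.sum(axis=0)
        dcols = (d @ self.params["W"].reshape(self.out_ch, -1)).reshape(
            n, ho, wo, self.in_ch, self.k, self.k)
        _, c, h, w_ = self._x_shape
        dxp = np.zeros((n, c, h + 2 * self.pad, w_ + 2 * self.pad))
        for ki in range(self.k):
            for kj in range(self.k):
                dxp[:, :, ki:ki + ho * self.stride:self.stride,
                    kj:kj + wo * self.stride:self.stride] += \
                    dcols[:, :, :, :, ki, kj].transpose(0, 3, 1, 2)
        return dxp[:, :, self.pad:self.pad + h, self.pad:self.pad + w_]


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class GlobalAvgPool(Layer):
    """(N, C, H, W) -> (N, C)."""

    def forward(self, x):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dout):
        n, c, h, w = self._shape
        return np.broadcast_to(dout[:, :, None, None], self._shape) / (h * w)


class Linear(Layer):
    def __init__(self, n_in: int, n_out: int, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.params["W"] = rng.normal(0, np.sqrt(1.0 / n_in), size=(n_out, n_in))
        self.params["b"] = np.zeros(n_out)
        self.zero_grad()

    def forward(self, x):
        self._x = x
        return x @ self.params["W"].T + self.params["b"]

    def backward(self, dout):
        self.grads["W"] += dout.T @ self._x
        self.grads["b"] += dout.sum(axis=0)
        return dout @ self.params["W"]


class ResidualBlock(Layer):
    """conv–ReLU–conv with identity skip, then ReLU; channel-preserving."""

    def __init__(self, channels: int, rng=None):
        super().__init__()
        self.conv1 = Conv2d(channels, channels, rng=rng)
        self.relu1 = ReLU()
        self.conv2 = Conv2d(channels, channels, rng=rng)
        self.relu2 = ReLU()
        self.children = [self.conv1, self.conv2]

    def zero_grad(self):
        for c in self.children:
            c.zero_grad()

    def forward(self, x):
        y = self.conv2.forward(self.relu1.forward(self.conv1.forward(x)))
        return self.relu2.forward(x + y)

    def backward(self, dout):
        d = self.relu2.backward(dout)
        dy = self.conv1.backward(self.relu1.backward(self.conv2.backward(d)))
        return d + dy


class LSTMCell(Layer):
    """One LSTM layer's parameters (input, forget, cell, output gates)."""

    def __init__(self, n_in: int, hidden: int, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.n_in, self.hidden = n_in, hidden
        scale = np.sqrt(1.0 / (n_in + hidden))
        self.params["Wx"] = rng.normal(0, scale, size=(4 * hidden, n_in))
        self.params["Wh"] = rng.normal(0, scale, size=(4 * hidden, hidden))
        self.params["b"] = np.zeros(4 * hidden)
        # forget-gate bias starts at 1 (standard trick for gradient flow)
        self.params["b"][hidden:2 * hidden] = 1.0
        self.zero_grad()


def lstm_forward(cell: LSTMCell, x: np.ndarray):
    """Unrolled LSTM over x (B, T, d) from zero state.

    Returns (h_last, cache); gate order in the stacked weights is
    [input i, forget f, candidate g, output o].
    """
    b, t, _d = x.shape
    m = cell.hidden
    h = np.zeros((b, m))
    c = np.zeros((b, m))
    cache = []
    wx, wh, bias = cell.params["Wx"], cell.params["Wh"], cell.params["b"]
    for step in range(t):
        z = x[:, step] @ wx.T + h @ wh.T + bias
        i = sigmoid(z[:, :m])
        f = sigmoid(z[:, m:2 * m])
        g = np.tanh(z[:, 2 * m:3 * m])
        o = sigmoid(z[:, 3 * m:])
        c_new = f * c + i * g
        h_new = o * np.tanh(c_new)
        cache.append((x[:, step], h, c, i, f, g, o, c_new))
        h, c = h_new, c_new
    return h, cache


def lstm_backward(cell: LSTMCell, dh_last: np.ndarray, cache) -> np.ndarray:
    """BPTT from a gradient on the final hidden state only.

    Returns the gradient with respect to the input sequence (B, T, d).
    """
    m = cell.hidden
    wx, wh = cell.params["Wx"], cell.params["Wh"]
    dh = dh_last
    dc = np.zeros_like(dh_last)
    dx = np.zeros((dh_last.shape[0], len(cache), cell.n_in))
    for step in range(len(cache) - 1, -1, -1):
        x_t, h_prev, c_prev, i, f, g, o, c_new = cache[step]
        tanh_c = np.tanh(c_new)
        do = dh * tanh_c
        dc = dc + dh * o * (1 - tanh_c ** 2)
        di, df, dg = dc * g, dc * c_prev, dc * i
        dz = np.concatenate(
            [di * i * (1 - i), df * f * (1 - f), dg * (1 - g ** 2),
             do * o * (1 - o)], axis=1)
        cell.grads["Wx"] += dz.T @ x_t
        cell.grads["Wh"] += dz.T @ h_prev
        cell.grads["b"] += dz.sum(axis=0)
        dx[:, step] = dz @ wx
        dh = dz @ wh
        dc = dc * f
    return dx


class Adam:
    """Adam over a list of layers carrying params/grads dicts."""

    def __init__(self, layers, lr: float = 1e-2, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.entries = []
        for layer in layers:
            for sub in getattr(layer, "children", [layer]):
                for key in sub.params:
                    self.entries.append((sub, key))
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(sub.params[k]) for sub, k in self.entries]
        self.v = [np.zeros_like(sub.params[k]) for sub, k in self.entries]
        self.t = 0

    def step(self):
        self.t += 1
        for idx, (sub, key) in enumerate(self.entries):
            g = sub.grads[key]
            self.m[idx] = self.b1 * self.m[idx] + (1 - self.b1) * g
            self.v[idx] = self.b2 * self.v[idx] + (1 - self.b2) * g * g
            mhat = self.m[idx] / (1 - self.b1 ** self.t)
            vhat = self.v[idx] / (1 - self.b2 ** self.t)
            sub.params[key] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for sub, _ in self.entries:
            sub.zero_grad()
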