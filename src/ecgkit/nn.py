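"""Minimal neural-network building blocks on numpy.

Implements exactly the layers the toolkit needs — 3x3 convolutions with
stride, ReLU, global average pooling, dense layers, a softmax cross-entropy
head, an LSTM cell with full backpropagation-through-time, and an Adam
optimizer.  Everything is float32, CPU-only, and deterministic given the
``numpy.random.Generator`` used for initialization and shuffling.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv2d",
    "ReLU",
    "GlobalAvgPool",
    "Dense",
    "Sequential",
    "BiLSTM",
    "Adam",
    "softmax",
    "softmax_xent",
]


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_xent(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over rows and its gradient w.r.t. the logits."""
    p = softmax(logits)
    n = logits.shape[0]
    loss = -np.mean(np.log(p[np.arange(n), labels] + 1e-12))
    dlogits = p.copy()
    dlogits[np.arange(n), labels] -= 1.0
    return float(loss), dlogits / n


class Layer:
    def params(self) -> list[tuple[np.ndarray, np.ndarray]]:
        """(value, gradient) pairs; gradients are filled by backward()."""
        return []


class Conv2d(Layer):
    """3x3 convolution, padding 1, configurable stride; He-initialized."""

    def __init__(self, cin: int, cout: int, stride: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (cin * 9))
        self.W = (rng.standard_normal((cout, cin, 3, 3)) * scale).astype(np.float32)
        self.b = np.zeros(cout, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.stride = stride

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]

    def _cols(self, xp: np.ndarray, ho: int, wo: int) -> np.ndarray:
        s = self.stride
        n, c = xp.shape[:2]
        cols = np.empty((n, c, 9, ho, wo), dtype=np.float32)
        for a in range(3):
            for b in range(3):
                cols[:, :, a * 3 + b] = xp[:, :, a : a + s * ho : s, b : b + s * wo : s]
        return cols

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        s = self.stride
        ho, wo = (h - 1) // s + 1, (w - 1) // s + 1
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        cols = self._cols(xp, ho, wo).reshape(n, c * 9, ho * wo)
        self._cache = (cols, x.shape)
        y = np.einsum("of,nfp->nop", self.W.reshape(self.W.shape[0], -1), cols)
        return y.reshape(n, -1, ho, wo) + self.b[None, :, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        cols, xshape = self._cache
        n, c, h, w = xshape
        cout = dy.shape[1]
        ho, wo = dy.shape[2], dy.shape[3]
        dyf = dy.reshape(n, cout, ho * wo)
        self.db[:] = dyf.sum(axis=(0, 2))
        self.dW[:] = np.einsum("nop,nfp->of", dyf, cols).reshape(self.W.shape)
        dcols = np.einsum("of,nop->nfp", self.W.reshape(cout, -1), dyf)
        dcols = dcols.reshape(n, c, 9, ho, wo)
        dxp = np.zeros((n, c, h + 2, w + 2), dtype=np.float32)
        s = self.stride
        for a in range(3):
            for b in range(3):
                dxp[:, :, a : a + s * ho : s, b : b + s * wo : s] += dcols[:, :, a * 3 + b]
        return dxp[:, :, 1 : h + 1, 1 : w + 1]


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class GlobalAvgPool(Layer):
    """(N, C, H, W) -> (N, C) by spatial mean."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        return np.broadcast_to(dy[:, :, None, None], self._shape) / (h * w)


class Dense(Layer):
    def __init__(self, din: int, dout: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / din)
        self.W = (rng.standard_normal((din, dout)) * scale).astype(np.float32)
        self.b = np.zeros(dout, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.dW[:] = self._x.T @ dy
        self.db[:] = dy.sum(axis=0)
        return dy @ self.W.T


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def params(self):
        out = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


class _LstmDirection(Layer):
    """Single-direction LSTM over a (T, D) sequence, hidden size H.

    Gate order in the fused weight matrices is input, forget, cell, output.
    """

    def __init__(self, din: int, hidden: int, rng: np.random.Generator):
        s = 1.0 / np.sqrt(din + hidden)
        self.Wx = (rng.standard_normal((din, 4 * hidden)) * s).astype(np.float32)
        self.Wh = (rng.standard_normal((hidden, 4 * hidden)) * s).astype(np.float32)
        self.b = np.zeros(4 * hidden, dtype=np.float32)
        self.b[hidden : 2 * hidden] = 1.0  # forget-gate bias
        self.dWx = np.zeros_like(self.Wx)
        self.dWh = np.zeros_like(self.Wh)
        self.db = np.zeros_like(self.b)
        self.hidden = hidden

    def params(self):
        return [(self.Wx, self.dWx), (self.Wh, self.dWh), (self.b, self.db)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        T, _ = x.shape
        H = self.hidden
        h = np.zeros(H, dtype=np.float32)
        c = np.zeros(H, dtype=np.float32)
        hs = np.zeros((T, H), dtype=np.float32)
        cache = []
        for t in range(T):
            z = x[t] @ self.Wx + h @ self.Wh + self.b
            i, f = _sigmoid(z[:H]), _sigmoid(z[H : 2 * H])
            g, o = np.tanh(z[2 * H : 3 * H]), _sigmoid(z[3 * H :])
            c_new = f * c + i * g
            tc = np.tanh(c_new)
            h_new = o * tc
            cache.append((x[t], h, c, i, f, g, o, c_new, tc))
            h, c = h_new, c_new
            hs[t] = h
        self._cache = cache
        return hs

    def backward(self, dhs: np.ndarray) -> np.ndarray:
        cache = self._cache
        T = len(cache)
        H = self.hidden
        self.dWx[:] = 0.0
        self.dWh[:] = 0.0
        self.db[:] = 0.0
        dx = np.zeros((T, self.Wx.shape[0]), dtype=np.float32)
        dh_next = np.zeros(H, dtype=np.float32)
        dc_next = np.zeros(H, dtype=np.float32)
        for t in range(T - 1, -1, -1):
            xt, h_prev, c_prev, i, f, g, o, c_new, tc = cache[t]
            dh = dhs[t] + dh_next
            do = dh * tc
            dc = dh * o * (1.0 - tc * tc) + dc_next
            di, df, dg = dc * g, dc * c_prev, dc * i
            dz = np.concatenate(
                [
                    di * i * (1 - i),
                    df * f * (1 - f),
                    dg * (1 - g * g),
                    do * o * (1 - o),
                ]
            ).astype(np.float32)
            self.dWx += np.outer(xt, dz)
            self.dWh += np.outer(h_prev, dz)
            self.db += dz
            dx[t] = dz @ self.Wx.T
            dh_next = dz @ self.Wh.T
            dc_next = dc * f
        return dx


class BiLSTM(Layer):
    """Bidirectional LSTM: (T, D) -> (T, 2H) by forward/backward concatenation."""

    def __init__(self, din: int, hidden: int, rng: np.random.Generator):
        self.fwd = _LstmDirection(din, hidden, rng)
        self.bwd = _LstmDirection(din, hidden, rng)
        self.hidden = hidden

    def params(self):
        return self.fwd.params() + self.bwd.params()

    def forward(self, x: np.ndarray) -> np.ndarray:
        hf = self.fwd.forward(x)
        hb = self.bwd.forward(x[::-1])[::-1]
        return np.concatenate([hf, hb], axis=1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        H = self.hidden
        dxf = self.fwd.backward(dy[:, :H])
        dxb = self.bwd.backward(dy[::-1, H:])[::-1]
        return dxf + dxb


class Adam:
    """Adam over the (value, grad) pairs exposed by a model's params()."""

    def __init__(self, params, lr: float = 1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        for k, (p, g) in enumerate(self.params):
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
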