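"""Layer primitives with explicit forward/backward passes.

Conventions: channels-last tensors; convolutions are stride-1 with TF-style
'same' zero padding (spatial size changes only at pools); the input gradient
of a convolution is computed as a full correlation with the flipped kernel,
which reuses the same im2col machinery as the forward pass.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def glorot_uniform(rng: np.random.Generator, shape, fan_in: int, fan_out: int):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def _sigmoid(x):
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _im2col(x: np.ndarray, kh: int, kw: int) -> np.ndarray:
    """[B, H, W, C] -> [B, H-kh+1, W-kw+1, kh*kw*C] patch matrix."""
    v = sliding_window_view(x, (kh, kw), axis=(1, 2))  # [B, Ho, Wo, C, kh, kw]
    v = v.transpose(0, 1, 2, 4, 5, 3)  # [B, Ho, Wo, kh, kw, C]
    b, ho, wo = v.shape[:3]
    return np.ascontiguousarray(v).reshape(b, ho, wo, kh * kw * x.shape[3])


class Layer:
    trainable = False

    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv2D(Layer):
    """Stride-1 'same' convolution with optional ReLU and L2 weight penalty."""

    trainable = True

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel: tuple[int, int],
        rng: np.random.Generator,
        activation: str = "relu",
        l2: float = 0.0,
        dtype=np.float64,
        input_grad: bool = True,
    ):
        kh, kw = kernel
        fan_in = kh * kw * in_channels
        fan_out = kh * kw * out_channels
        self.W = glorot_uniform(rng, (kh * kw * in_channels, out_channels), fan_in, fan_out).astype(dtype)
        self.b = np.zeros(out_channels, dtype=dtype)
        self.kernel = kernel
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.activation = activation
        self.l2 = l2
        self.input_grad = input_grad  # first layer can skip its dx
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        # TF-style same padding for stride 1: total = k - 1
        self.pt, self.pl = (kh - 1) // 2, (kw - 1) // 2
        self.pb, self.pr = kh - 1 - self.pt, kw - 1 - self.pl

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def l2_loss(self) -> float:
        return float(self.l2 * np.sum(self.W.astype(np.float64) ** 2))

    def forward(self, x, training=False):
        kh, kw = self.kernel
        xp = np.pad(x, ((0, 0), (self.pt, self.pb), (self.pl, self.pr), (0, 0)))
        cols = _im2col(xp, kh, kw)  # [B, H, W, kh*kw*Cin]
        self._cols = cols
        out = cols @ self.W + self.b
        if self.activation == "relu":
            self._mask = out > 0
            out = out * self._mask
        return out

    def backward(self, dout):
        kh, kw = self.kernel
        if self.activation == "relu":
            dout = dout * self._mask
        b, h, w, _ = dout.shape
        cols2d = self._cols.reshape(-1, self.W.shape[0])
        dout2d = dout.reshape(-1, self.out_channels)
        self.dW[...] = cols2d.T @ dout2d
        if self.l2:
            self.dW += 2.0 * self.l2 * self.W
        self.db[...] = dout2d.sum(axis=0)
        if not self.input_grad:
            return None

        # dx = full correlation of dout with the flipped kernel
        Wk = self.W.reshape(kh, kw, self.in_channels, self.out_channels)
        Wb = Wk[::-1, ::-1].transpose(0, 1, 3, 2).reshape(kh * kw * self.out_channels, self.in_channels)
        dyp = np.pad(dout, ((0, 0), (kh - 1, kh - 1), (kw - 1, kw - 1), (0, 0)))
        dxp = _im2col(dyp, kh, kw) @ Wb  # [B, H+kh-1, W+kw-1, Cin]
        return dxp[:, self.pt : self.pt + h, self.pl : self.pl + w, :]


class MaxPool2D(Layer):
    """Non-overlapping max pool with floor cropping (stride = pool size)."""

    def __init__(self, pool: tuple[int, int]):
        self.pool = pool

    @staticmethod
    def out_size(size: int, pool: int) -> int:
        return size // pool

    def forward(self, x, training=False):
        ph, pw = self.pool
        b, h, w, c = x.shape
        ho, wo = h // ph, w // pw
        self._in_shape = x.shape
        xr = x[:, : ho * ph, : wo * pw, :].reshape(b, ho, ph, wo, pw, c)
        xt = xr.transpose(0, 1, 3, 5, 2, 4).reshape(b, ho, wo, c, ph * pw)
        self._argmax = np.argmax(xt, axis=-1)
        out = np.take_along_axis(xt, self._argmax[..., None], axis=-1)[..., 0]
        return out

    def backward(self, dout):
        ph, pw = self.pool
        b, h, w, c = self._in_shape
        ho, wo = h // ph, w // pw
        dxt = np.zeros((b, ho, wo, c, ph * pw), dtype=dout.dtype)
        np.put_along_axis(dxt, self._argmax[..., None], dout[..., None], axis=-1)
        dxr = dxt.reshape(b, ho, wo, c, ph, pw).transpose(0, 1, 4, 2, 5, 3)
        dx = np.zeros(self._in_shape, dtype=dout.dtype)
        dx[:, : ho * ph, : wo * pw, :] = dxr.reshape(b, ho * ph, wo * pw, c)
        return dx


class Dense(Layer):
    """Affine map over the last axis, optional ReLU."""

    trainable = True

    def __init__(
        self,
        in_features: int,
        out_features: int,
        rng: np.random.Generator,
        activation: str | None = None,
        dtype=np.float64,
    ):
        self.W = glorot_uniform(rng, (in_features, out_features), in_features, out_features).astype(dtype)
        self.b = np.zeros(out_features, dtype=dtype)
        self.activation = activation
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def forward(self, x, training=False):
        self._shape = x.shape
        x2 = x.reshape(-1, self.W.shape[0])
        self._x2 = x2
        out = x2 @ self.W + self.b
        if self.activation == "relu":
            self._mask = out > 0
            out = out * self._mask
        return out.reshape(*x.shape[:-1], self.W.shape[1])

    def backward(self, dout):
        dout2 = dout.reshape(-1, self.W.shape[1])
        if self.activation == "relu":
            dout2 = dout2 * self._mask
        self.dW[...] = self._x2.T @ dout2
        self.db[...] = dout2.sum(axis=0)
        return (dout2 @ self.W.T).reshape(self._shape)


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float, rng: np.random.Generator):
        self.rate = rate
        self.rng = rng
        self._mask = None

    def forward(self, x, training=False):
        if not training or self.rate <= 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, dout):
        if self._mask is None:
            return dout
        return dout * self._mask


class LSTM(Layer):
    """Single-layer LSTM over [B, S, D] -> [B, S, U], state reset per batch."""

    trainable = True

    def __init__(self, in_features: int, units: int, rng: np.random.Generator, dtype=np.float64):
        U = units
        self.units = U
        self.Wx = glorot_uniform(rng, (in_features, 4 * U), in_features, U).astype(dtype)
        self.Wh = glorot_uniform(rng, (U, 4 * U), U, U).astype(dtype)
        self.b = np.zeros(4 * U, dtype=dtype)
        self.b[U : 2 * U] = 1.0  # forget-gate bias
        self.dWx = np.zeros_like(self.Wx)
        self.dWh = np.zeros_like(self.Wh)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [self.Wx, self.Wh, self.b]

    def grads(self):
        return [self.dWx, self.dWh, self.db]

    def forward(self, x, training=False):
        B, S, D = x.shape
        U = self.units
        h = np.zeros((B, U), dtype=x.dtype)
        c = np.zeros((B, U), dtype=x.dtype)
        self._x = x
        self._cache = []
        out = np.empty((B, S, U), dtype=x.dtype)
        xw = x @ self.Wx  # [B, S, 4U] precomputed input contribution
        for t in range(S):
            z = xw[:, t] + h @ self.Wh + self.b
            i = _sigmoid(z[:, :U])
            f = _sigmoid(z[:, U : 2 * U])
            g = np.tanh(z[:, 2 * U : 3 * U])
            o = _sigmoid(z[:, 3 * U :])
            c_prev, h_prev = c, h
            c = f * c_prev + i * g
            tc = np.tanh(c)
            h = o * tc
            out[:, t] = h
            self._cache.append((h_prev, c_prev, i, f, g, o, tc))
        return out

    def backward(self, dout):
        x = self._x
        B, S, D = x.shape
        U = self.units
        self.dWx[...] = 0.0
        self.dWh[...] = 0.0
        self.db[...] = 0.0
        dx = np.empty_like(x)
        dh_next = np.zeros((B, U), dtype=x.dtype)
        dc_next = np.zeros((B, U), dtype=x.dtype)
        dz = np.empty((B, 4 * U), dtype=x.dtype)
        for t in range(S - 1, -1, -1):
            h_prev, c_prev, i, f, g, o, tc = self._cache[t]
            dh = dout[:, t] + dh_next
            do = dh * tc
            dc = dh * o * (1.0 - tc * tc) + dc_next
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dc_next = dc * f
            dz[:, :U] = di * i * (1.0 - i)
            dz[:, U : 2 * U] = df * f * (1.0 - f)
            dz[:, 2 * U : 3 * U] = dg * (1.0 - g * g)
            dz[:, 3 * U :] = do * o * (1.0 - o)
            self.dWx += x[:, t].T @ dz
            self.dWh += h_prev.T @ dz
            self.db += dz.sum(axis=0)
            dx[:, t] = dz @ self.Wx.T
            dh_next = dz @ self.Wh.T
        return dx


def softmax(logits: np.ndarray) -> np.ndarray:
    """Numerically stabilized softmax over the last axis."""
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(
    logits: np.ndarray, labels: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean cross-entropy and its gradient w.r.t. the logits.

    ``logits``: [N, K]; ``labels``: [N] integer classes.
    """
    n = logits.shape[0]
    p = softmax(logits)
    eps = np.finfo(p.dtype).tiny
    loss = -float(np.mean(np.log(p[np.arange(n), labels] + eps)))
    dlogits = p.copy()
    dlogits[np.arange(n), labels] -= 1.0
    return loss, dlogits / n


class Adam:
    """Adam with bias correction."""

    def __init__(self, params: list[np.ndarray], lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
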