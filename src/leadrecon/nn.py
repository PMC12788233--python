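"""Minimal numpy neural-network core: layers with explicit backprop.

Implements exactly what the reconstruction models need — 1-D convolution
(same padding, via im2col), dense layers, a bidirectional LSTM, ReLU,
dropout, max-pool / nearest-upsample for the U-Net — plus the Adam
optimizer.  Every layer caches its forward activations and implements
``backward`` analytically; the gradients are verified against central
differences in the test suite.

Conventions: time-series tensors are ``(batch, channels, time)`` at the
model surface and ``(batch, time, features)`` inside recurrent layers;
parameters are stored in the module working precision ``DTYPE``.
"""

from __future__ import annotations

import numpy as np

#: working floating-point precision of the layer library.  float32 is the
#: training default (the signals span ~1e-2..2 mV, far from float32 limits);
#: gradient-check tests switch to float64 for central differences.
DTYPE = np.float32


def set_default_dtype(dtype) -> None:
    global DTYPE
    DTYPE = np.dtype(dtype).type


class Param:
    __slots__ = ("name", "value", "grad")

    def __init__(self, name: str, value: np.ndarray):
        self.name = name
        self.value = value
        self.grad = np.zeros_like(value)


def glorot(rng: np.random.Generator, shape: tuple[int, ...],
           fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(DTYPE)


class Layer:
    def params(self) -> list[Param]:
        return []

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0.0


class Dense(Layer):
    """Affine map on the last axis (time-distributed when input is 3-D)."""

    def __init__(self, rng: np.random.Generator, cin: int, cout: int, name: str = "dense"):
        self.w = Param(f"{name}.w", glorot(rng, (cin, cout), cin, cout))
        self.b = Param(f"{name}.b", np.zeros(cout, dtype=DTYPE))
        self._x = None

    def params(self):
        return [self.w, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, gy: np.ndarray) -> np.ndarray:
        x = self._x
        x2 = x.reshape(-1, x.shape[-1])
        g2 = gy.reshape(-1, gy.shape[-1])
        self.w.grad += x2.T @ g2
        self.b.grad += g2.sum(axis=0)
        return gy @ self.w.value.T


class Conv1d(Layer):
    """Same-padded 1-D convolution over (batch, channels, time)."""

    def __init__(self, rng: np.random.Generator, cin: int, cout: int, k: int,
                 name: str = "conv"):
        if k % 2 != 1:
            raise ValueError("kernel size must be odd for same padding")
        self.k = k
        self.cin = cin
        self.w = Param(f"{name}.w", glorot(rng, (cin * k, cout), cin * k, cout))
        self.b = Param(f"{name}.b", np.zeros(cout, dtype=DTYPE))
        self._cols = None
        self._shape = None

    def params(self):
        return [self.w, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, c, t = x.shape
        pad = self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (pad, pad)))
        # (B, C, T, k) -> (B, T, C, k)
        cols = np.lib.stride_tricks.sliding_window_view(xp, self.k, axis=2)
        cols = cols.transpose(0, 2, 1, 3).reshape(b * t, c * self.k)
        self._cols = cols
        self._shape = (b, c, t)
        y = cols @ self.w.value + self.b.value
        return y.reshape(b, t, -1).transpose(0, 2, 1)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        b, c, t = self._shape
        g2 = gy.transpose(0, 2, 1).reshape(b * t, -1)
        self.w.grad += self._cols.T @ g2
        self.b.grad += g2.sum(axis=0)
        gcols = (g2 @ self.w.value.T).reshape(b, t, c, self.k)
        pad = self.k // 2
        gxp = np.zeros((b, c, t + 2 * pad), dtype=gy.dtype)
        for i in range(self.k):
            gxp[:, :, i:i + t] += gcols[:, :, :, i].transpose(0, 2, 1)
        return gxp[:, :, pad:pad + t]


class ReLU(Layer):
    def __init__(self):
        self._mask = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, gy: np.ndarray) -> np.ndarray:
        return gy * self._mask


class Dropout(Layer):
    """Inverted dropout.

    Active in ``train`` mode, and in ``mc`` mode when the layer is flagged as
    a Monte-Carlo site (the dropout layers after the BiLSTM block and after
    the fusion/concatenation block); a no-op in ``eval`` mode.
    """

    def __init__(self, p: float, mc_site: bool = False):
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.p = p
        self.mc_site = mc_site
        self._mask = None

    def forward(self, x: np.ndarray, mode: str, rng: np.random.Generator | None
                ) -> np.ndarray:
        active = self.p > 0 and (mode == "train" or (mode == "mc" and self.mc_site))
        if not active:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("active dropout requires an rng")
        self._mask = (rng.random(x.shape) >= self.p).astype(x.dtype) / \
            x.dtype.type(1.0 - self.p)
        return x * self._mask

    def backward(self, gy: np.ndarray) -> np.ndarray:
        return gy if self._mask is None else gy * self._mask


class LSTM(Layer):
    """Single-direction LSTM over (batch, time, features); returns h per step.

    Gate layout inside the fused weight matrices is (i, f, o, g) so the three
    sigmoid gates can be activated in a single call per step.
    """

    def __init__(self, rng: np.random.Generator, cin: int, hidden: int,
                 name: str = "lstm"):
        self.h = hidden
        self.wx = Param(f"{name}.wx", glorot(rng, (cin, 4 * hidden), cin, 4 * hidden))
        self.wh = Param(f"{name}.wh", glorot(rng, (hidden, 4 * hidden), hidden, 4 * hidden))
        b = np.zeros(4 * hidden, dtype=DTYPE)
        b[hidden:2 * hidden] = 1.0  # forget-gate bias
        self.b = Param(f"{name}.b", b)
        self._cache = None

    def params(self):
        return [self.wx, self.wh, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        from scipy.special import expit

        bsz, t, cin = x.shape
        h = self.h
        xz = x.reshape(-1, cin) @ self.wx.value + self.b.value
        xz = xz.reshape(bsz, t, 4 * h)
        dt = x.dtype
        gates = np.empty((t, bsz, 4 * h), dtype=dt)  # sigmoid(i,f,o), tanh(g)
        cs = np.empty((t, bsz, h), dtype=dt); tc = np.empty((t, bsz, h), dtype=dt)
        hs = np.empty((t, bsz, h), dtype=dt)
        hp = np.zeros((bsz, h), dtype=dt); cp = np.zeros((bsz, h), dtype=dt)
        wh = self.wh.value
        for k in range(t):
            z = xz[:, k] + hp @ wh
            zk = gates[k]
            expit(z[:, :3 * h], out=zk[:, :3 * h])
            np.tanh(z[:, 3 * h:], out=zk[:, 3 * h:])
            c = zk[:, h:2 * h] * cp + zk[:, :h] * zk[:, 3 * h:]
            tch = np.tanh(c, out=tc[k])
            hcur = np.multiply(zk[:, 2 * h:3 * h], tch, out=hs[k])
            cs[k] = c
            hp, cp = hcur, c
        self._cache = (x, gates, cs, tc, hs)
        return hs.transpose(1, 0, 2)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        x, gates, cs, tc, hs = self._cache
        bsz, t, cin = x.shape
        h = self.h
        gy = gy.transpose(1, 0, 2)  # (T, B, H)
        dt = x.dtype
        dz_all = np.empty((t, bsz, 4 * h), dtype=dt)
        dh_next = np.zeros((bsz, h), dtype=dt)
        dc_next = np.zeros((bsz, h), dtype=dt)
        whT = self.wh.value.T
        zeros = np.zeros((bsz, h), dtype=dt)
        for k in range(t - 1, -1, -1):
            dh = gy[k] + dh_next
            zk = gates[k]
            i, f, o, g = (zk[:, :h], zk[:, h:2 * h], zk[:, 2 * h:3 * h],
                          zk[:, 3 * h:])
            tch = tc[k]
            cprev = cs[k - 1] if k > 0 else zeros
            do = dh * tch
            dc = dc_next + dh * o * (1.0 - tch * tch)
            dz = dz_all[k]
            dz[:, :h] = dc * g * i * (1 - i)
            dz[:, h:2 * h] = dc * cprev * f * (1 - f)
            dz[:, 2 * h:3 * h] = do * o * (1 - o)
            dz[:, 3 * h:] = dc * i * (1 - g * g)
            dc_next = dc * f
            dh_next = dz @ whT
        hprev = np.concatenate([np.zeros((1, bsz, h), dtype=dt), hs[:-1]], axis=0)
        self.wh.grad += np.einsum("tbh,tbk->hk", hprev, dz_all)
        dz_flat = dz_all.transpose(1, 0, 2).reshape(-1, 4 * h)
        self.wx.grad += x.reshape(-1, cin).T @ dz_flat
        self.b.grad += dz_flat.sum(axis=0)
        return (dz_flat @ self.wx.value.T).reshape(bsz, t, cin)


class BiLSTM(Layer):
    """Forward + time-reversed LSTM, hidden states concatenated per step."""

    def __init__(self, rng: np.random.Generator, cin: int, hidden: int,
                 name: str = "bilstm"):
        self.fw = LSTM(rng, cin, hidden, name=f"{name}.fw")
        self.bw = LSTM(rng, cin, hidden, name=f"{name}.bw")
        self.h = hidden

    def params(self):
        return self.fw.params() + self.bw.params()

    def forward(self, x: np.ndarray) -> np.ndarray:
        hf = self.fw.forward(x)
        hb = self.bw.forward(x[:, ::-1])[:, ::-1]
        return np.concatenate([hf, hb], axis=2)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        h = self.h
        gxf = self.fw.backward(gy[:, :, :h])
        gxb = self.bw.backward(gy[:, ::-1, h:])[:, ::-1]
        return gxf + gxb


class MaxPool1d(Layer):
    """Max pooling by 2 over (batch, channels, time); time must be even."""

    def __init__(self):
        self._arg = None
        self._shape = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, c, t = x.shape
        xr = x.reshape(b, c, t // 2, 2)
        self._arg = xr.argmax(axis=3)
        self._shape = (b, c, t)
        return xr.max(axis=3)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        b, c, t = self._shape
        g = np.zeros((b, c, t // 2, 2), dtype=gy.dtype)
        np.put_along_axis(g, self._arg[..., None], gy[..., None], axis=3)
        return g.reshape(b, c, t)


class Upsample1d(Layer):
    """Nearest-neighbour upsampling by 2 over (batch, channels, time)."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        return np.repeat(x, 2, axis=2)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        b, c, t = gy.shape
        return gy.reshape(b, c, t // 2, 2).sum(axis=3)


class Adam:
    """Adam optimizer over a flat parameter list."""

    def __init__(self, params: list[Param], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            m[...] = b1 * m + (1 - b1) * p.grad
            v[...] = b2 * v + (1 - b2) * p.grad ** 2
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    from scipy.special import expit

    return expit(x)
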