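"""Minimal NumPy neural-network engine used by the 2D segmentation networks
and the 1D spectral classifier.

Design: explicit layer objects with ``forward``/``backward`` methods and a
flat parameter list, rather than a tape-based autograd.  Convolutions are
implemented as im2col + GEMM in float32, which keeps both training loops on
the BLAS fast path of a single CPU.  All initialisation is driven by a
``numpy.random.Generator`` so that two builds from the same seed produce
bit-identical parameters.

Every layer's backward pass is exercised by finite-difference gradient
checks in the test suite.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

DTYPE = np.float32


class Param:
    """A trainable tensor with its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.ascontiguousarray(value, dtype=DTYPE)
        self.grad = np.zeros_like(self.value)


def glorot_uniform(rng: np.random.Generator, shape, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(DTYPE)


def he_normal(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(DTYPE)


class Module:
    """Base class: a differentiable block with parameters."""

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    __call__ = forward

    def modules(self):
        """This module and its children (containers override)."""
        yield self

    def buffers(self) -> list[np.ndarray]:
        """Non-trained state arrays (e.g. batch-norm running statistics)."""
        return []

    def all_buffers(self) -> list[np.ndarray]:
        return [b for m in self.modules() for b in m.buffers()]

    # --- model state (parameters + buffers) for snapshots and checkpoints ---
    def get_state(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.params()] + \
            [b.copy() for b in self.all_buffers()]

    def set_state(self, state: list[np.ndarray]) -> None:
        own = [p.value for p in self.params()] + self.all_buffers()
        if len(own) != len(state):
            raise ValueError(f"state has {len(state)} arrays, model has {len(own)}")
        for p, v in zip(own, state):
            if p.shape != v.shape:
                raise ValueError(f"shape mismatch: {p.shape} vs {v.shape}")
            p[...] = v

    def n_params(self) -> int:
        return int(sum(p.value.size for p in self.params()))


class Sequential(Module):
    def __init__(self, *layers: Module):
        self.layers = list(layers)

    def params(self):
        out = []
        for l in self.layers:
            out.extend(l.params())
        return out

    def modules(self):
        yield self
        for l in self.layers:
            yield from l.modules()

    def forward(self, x, train=True):
        for l in self.layers:
            x = l.forward(x, train=train)
        return x

    def backward(self, grad):
        for l in reversed(self.layers):
            grad = l.backward(grad)
        return grad


# ---------------------------------------------------------------------------
# Elementwise activations
# ---------------------------------------------------------------------------

class ReLU(Module):
    def forward(self, x, train=True):
        self._mask = x > 0
        return np.where(self._mask, x, 0)

    def backward(self, grad):
        return np.where(self._mask, grad, 0)


class Tanh(Module):
    def forward(self, x, train=True):
        self._y = np.tanh(x)
        return self._y

    def backward(self, grad):
        return grad * (1.0 - self._y * self._y)


class Sigmoid(Module):
    def forward(self, x, train=True):
        self._y = sigmoid(x)
        return self._y

    def backward(self, grad):
        return grad * self._y * (1.0 - self._y)


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=DTYPE)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    e = np.exp(x[~pos])
    out[~pos] = e / (1.0 + e)
    return out


# ---------------------------------------------------------------------------
# Dense / 1D layers
# ---------------------------------------------------------------------------

class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = Param(glorot_uniform(rng, (n_in, n_out), n_in, n_out))
        self.b = Param(np.zeros(n_out, dtype=DTYPE))

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train=True):
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, grad):
        self.W.grad += self._x.T @ grad
        self.b.grad += grad.sum(axis=0)
        return grad @ self.W.value.T


class Conv1d(Module):
    """Same-padded, stride-1 1D convolution over (B, L, C) channels-last
    tensors (the layout keeps both GEMM operands contiguous)."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator,
                 input_grad: bool = True):
        if k % 2 != 1:
            raise ValueError("kernel size must be odd for same padding")
        self.c_in, self.c_out, self.k = c_in, c_out, k
        self.input_grad = input_grad  # first layers can skip the dx GEMM
        fan_in, fan_out = c_in * k, c_out * k
        self.W = Param(glorot_uniform(rng, (c_in * k, c_out), fan_in, fan_out))
        self.b = Param(np.zeros(c_out, dtype=DTYPE))

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train=True):
        # shifted-GEMM formulation: one full-length GEMM per kernel tap on
        # the zero-padded input, accumulated through shifted views — no
        # im2col materialisation
        B, L, C = x.shape
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (p, p), (0, 0)))
        self._xp, self._shape = xp, (B, L, C)
        W3 = self.W.value.reshape(C, self.k, self.c_out)
        xp2 = xp.reshape(B * (L + 2 * p), C)
        y = np.empty((B, L, self.c_out), dtype=DTYPE)
        y[...] = self.b.value
        for t in range(self.k):
            z = (xp2 @ W3[:, t, :]).reshape(B, L + 2 * p, self.c_out)
            y += z[:, t:t + L]
        return y

    def backward(self, grad):
        B, L, C = self._shape
        p = self.k // 2
        Lp = L + 2 * p
        g2 = grad.reshape(B * L, self.c_out)
        self.b.grad += g2.sum(axis=0)
        # dW tap t pairs xp rows j with grad rows j - t (within a batch
        # item).  Flattening across items with an extra p rows of zeros at
        # each end makes every tap a single offset GEMM: rows that bleed
        # across an item boundary always multiply zero padding rows of xp.
        galloc = np.zeros((B * Lp + 2 * p, self.c_out), dtype=DTYPE)
        gbig = galloc[p:p + B * Lp].reshape(B, Lp, self.c_out)
        gbig[:, p:p + L] = grad
        xp2 = self._xp.reshape(B * Lp, C)
        W3g = self.W.grad.reshape(C, self.k, self.c_out)
        for t in range(self.k):
            off = 2 * p - t
            W3g[:, t, :] += xp2.T @ galloc[off:off + B * Lp]
        if not self.input_grad:
            return None
        # dx: scatter each tap's contribution into the padded gradient
        W3 = self.W.value.reshape(C, self.k, self.c_out)
        dxp = np.zeros((B, Lp, C), dtype=DTYPE)
        for t in range(self.k):
            dxp[:, t:t + L] += (g2 @ W3[:, t, :].T).reshape(B, L, C)
        return np.ascontiguousarray(dxp[:, p:p + L])


class MaxPool1d(Module):
    """Non-overlapping max pooling along the length axis of (B, L, C)."""

    def __init__(self, size: int):
        self.size = size

    def forward(self, x, train=True):
        B, L, C = x.shape
        if L % self.size:
            raise ValueError(f"length {L} not divisible by pool size {self.size}")
        self._shape = x.shape
        if self.size == 2:   # branchless fast path
            a, b = x[:, ::2], x[:, 1::2]
            self._take_a = a >= b
            return np.where(self._take_a, a, b)
        xr = x.reshape(B, L // self.size, self.size, C)
        self._arg = xr.argmax(axis=2)
        return xr.max(axis=2)

    def backward(self, grad):
        B, L, C = self._shape
        out = np.zeros((B, L, C), dtype=DTYPE)
        if self.size == 2:
            out[:, ::2] = np.where(self._take_a, grad, 0)
            out[:, 1::2] = np.where(self._take_a, 0, grad)
            return out
        outr = out.reshape(B, L // self.size, self.size, C)
        np.put_along_axis(outr, self._arg[:, :, None], grad[:, :, None], axis=2)
        return out


class Flatten(Module):
    def forward(self, x, train=True):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


# ---------------------------------------------------------------------------
# 2D layers
# ---------------------------------------------------------------------------

class Conv2d(Module):
    """Same-padded, stride-1 2D convolution over (B, C, H, W) tensors."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator,
                 init: str = "he", input_grad: bool = True):
        if k % 2 != 1:
            raise ValueError("kernel size must be odd for same padding")
        self.c_in, self.c_out, self.k = c_in, c_out, k
        self.input_grad = input_grad
        fan_in = c_in * k * k
        if init == "he":
            self.W = Param(he_normal(rng, (fan_in, c_out), fan_in))
        else:
            self.W = Param(glorot_uniform(rng, (fan_in, c_out), fan_in, c_out * k * k))
        self.b = Param(np.zeros(c_out, dtype=DTYPE))

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train=True):
        B, C, H, W = x.shape
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        cols = sliding_window_view(xp, (self.k, self.k), axis=(2, 3))  # (B,C,H,W,k,k)
        cols = np.ascontiguousarray(cols.transpose(0, 2, 3, 1, 4, 5)).reshape(
            B * H * W, C * self.k * self.k)
        self._cols, self._shape = cols, (B, C, H, W)
        y = cols @ self.W.value + self.b.value
        return np.ascontiguousarray(y.reshape(B, H, W, self.c_out).transpose(0, 3, 1, 2))

    def backward(self, grad):
        B, C, H, W = self._shape
        g2 = np.ascontiguousarray(grad.transpose(0, 2, 3, 1)).reshape(B * H * W, self.c_out)
        self.W.grad += self._cols.T @ g2
        self.b.grad += g2.sum(axis=0)
        if not self.input_grad:
            return None
        p = self.k // 2
        gp = np.pad(grad, ((0, 0), (0, 0), (p, p), (p, p)))
        gcols = sliding_window_view(gp, (self.k, self.k), axis=(2, 3))
        gcols = np.ascontiguousarray(gcols.transpose(0, 2, 3, 1, 4, 5)).reshape(
            B * H * W, self.c_out * self.k * self.k)
        Wr = self.W.value.reshape(C, self.k, self.k, self.c_out)
        Wr = np.ascontiguousarray(
            Wr.transpose(3, 1, 2, 0)[:, ::-1, ::-1, :]).reshape(
            self.c_out * self.k * self.k, C)
        dx = (gcols @ Wr).reshape(B, H, W, C)
        return np.ascontiguousarray(dx.transpose(0, 3, 1, 2))


class ConvTranspose2d(Module):
    """2x up-sampling transpose convolution (kernel 2, stride 2)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        self.c_in, self.c_out = c_in, c_out
        fan_in = c_in  # each output pixel sees exactly one input pixel
        self.W = Param(he_normal(rng, (c_in, c_out * 4), fan_in))
        self.b = Param(np.zeros(c_out, dtype=DTYPE))

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train=True):
        B, C, H, W = x.shape
        self._x2 = np.ascontiguousarray(x.transpose(0, 2, 3, 1)).reshape(B * H * W, C)
        self._shape = (B, C, H, W)
        y = self._x2 @ self.W.value  # (BHW, c_out*4)
        y = y.reshape(B, H, W, self.c_out, 2, 2).transpose(0, 3, 1, 4, 2, 5)
        y = np.ascontiguousarray(y).reshape(B, self.c_out, 2 * H, 2 * W)
        return y + self.b.value[None, :, None, None]

    def backward(self, grad):
        B, C, H, W = self._shape
        self.b.grad += grad.sum(axis=(0, 2, 3))
        g = grad.reshape(B, self.c_out, H, 2, W, 2).transpose(0, 2, 4, 1, 3, 5)
        g = np.ascontiguousarray(g).reshape(B * H * W, self.c_out * 4)
        self.W.grad += self._x2.T @ g
        dx = (g @ self.W.value.T).reshape(B, H, W, C)
        return np.ascontiguousarray(dx.transpose(0, 3, 1, 2))


class MaxPool2d(Module):
    def __init__(self, size: int = 2):
        self.size = size

    def forward(self, x, train=True):
        B, C, H, W = x.shape
        s = self.size
        if H % s or W % s:
            raise ValueError(f"spatial shape {(H, W)} not divisible by pool size {s}")
        self._shape = x.shape
        if s == 2:   # branchless fast path over the four window corners
            q = (x[:, :, ::2, ::2], x[:, :, ::2, 1::2],
                 x[:, :, 1::2, ::2], x[:, :, 1::2, 1::2])
            t1 = q[0] >= q[1]
            m1 = np.where(t1, q[0], q[1])
            t2 = q[2] >= q[3]
            m2 = np.where(t2, q[2], q[3])
            t3 = m1 >= m2
            self._takes = (t1, t2, t3)
            return np.where(t3, m1, m2)
        xr = x.reshape(B, C, H // s, s, W // s, s).transpose(0, 1, 2, 4, 3, 5)
        xr = np.ascontiguousarray(xr).reshape(B, C, H // s, W // s, s * s)
        self._arg = xr.argmax(axis=4)
        return xr.max(axis=4)

    def backward(self, grad):
        B, C, H, W = self._shape
        s = self.size
        if s == 2:
            t1, t2, t3 = self._takes
            g1 = np.where(t3, grad, 0)
            g2 = grad - g1
            out = np.zeros((B, C, H, W), dtype=DTYPE)
            out[:, :, ::2, ::2] = np.where(t1, g1, 0)
            out[:, :, ::2, 1::2] = g1 - out[:, :, ::2, ::2]
            out[:, :, 1::2, ::2] = np.where(t2, g2, 0)
            out[:, :, 1::2, 1::2] = g2 - out[:, :, 1::2, ::2]
            return out
        out = np.zeros((B, C, H // s, W // s, s * s), dtype=DTYPE)
        np.put_along_axis(out, self._arg[..., None], grad[..., None], axis=4)
        out = out.reshape(B, C, H // s, W // s, s, s).transpose(0, 1, 2, 4, 3, 5)
        return np.ascontiguousarray(out).reshape(B, C, H, W)


class BatchNorm2d(Module):
    """Batch normalisation with EMA running statistics and an optional
    post-training calibration mode that replaces the EMA with exact pooled
    statistics over a reference set (small batches make the EMA noisy)."""

    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Param(np.ones(c, dtype=DTYPE))
        self.beta = Param(np.zeros(c, dtype=DTYPE))
        self.momentum, self.eps = momentum, eps
        self.running_mean = np.zeros(c, dtype=DTYPE)
        self.running_var = np.ones(c, dtype=DTYPE)
        self._calibrating = False

    def params(self):
        return [self.gamma, self.beta]

    def buffers(self):
        return [self.running_mean, self.running_var]

    def start_calibration(self):
        self._calibrating = True
        self._cal_mean = 0.0
        self._cal_sq = 0.0
        self._cal_n = 0

    def finish_calibration(self):
        if self._cal_n:
            mean = self._cal_mean / self._cal_n
            ex2 = self._cal_sq / self._cal_n
            self.running_mean[...] = mean.astype(DTYPE)
            self.running_var[...] = np.maximum(ex2 - mean ** 2, 0).astype(DTYPE)
        self._calibrating = False

    def forward(self, x, train=True):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            if self._calibrating:
                self._cal_mean = self._cal_mean + mean.astype(np.float64)
                self._cal_sq = self._cal_sq + (var + mean ** 2).astype(np.float64)
                self._cal_n += 1
            else:
                self.running_mean[...] = (
                    (1 - self.momentum) * self.running_mean
                    + self.momentum * mean).astype(DTYPE)
                self.running_var[...] = (
                    (1 - self.momentum) * self.running_var
                    + self.momentum * var).astype(DTYPE)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        self._inv = inv.astype(DTYPE)
        self._train = train
        return self.gamma.value[None, :, None, None] * self._xhat + \
            self.beta.value[None, :, None, None]

    def backward(self, grad):
        self.gamma.grad += (grad * self._xhat).sum(axis=(0, 2, 3))
        self.beta.grad += grad.sum(axis=(0, 2, 3))
        g = grad * self.gamma.value[None, :, None, None]
        if not self._train:
            return g * self._inv[None, :, None, None]
        B, C, H, W = grad.shape
        n = B * H * W
        gsum = g.sum(axis=(0, 2, 3))[None, :, None, None]
        gxsum = (g * self._xhat).sum(axis=(0, 2, 3))[None, :, None, None]
        return (self._inv[None, :, None, None] / n) * (
            n * g - gsum - self._xhat * gxsum)


def recalibrate_batchnorm(net: Module, batches) -> None:
    """Replace batch-norm running statistics with exact pooled statistics
    computed over the given forward batches (training-mode normalisation,
    no parameter updates)."""
    bns = [m for m in net.modules() if isinstance(m, BatchNorm2d)]
    if not bns:
        return
    for bn in bns:
        bn.start_calibration()
    for xb in batches:
        net.forward(xb, train=True)
    for bn in bns:
        bn.finish_calibration()


# ---------------------------------------------------------------------------
# Losses
# ---------------------------------------------------------------------------

def bce_with_logits(logits: np.ndarray, targets: np.ndarray):
    """Mean binary cross-entropy on raw scores; returns (loss, dloss/dlogits)."""
    z, t = logits.astype(np.float64), targets.astype(np.float64)
    loss = np.mean(np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z))))
    grad = ((sigmoid(logits.astype(DTYPE)) - targets) / logits.size).astype(DTYPE)
    return float(loss), grad


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean cross-entropy over integer class labels; returns (loss, grad, probs)."""
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    probs = e / e.sum(axis=1, keepdims=True)
    n = logits.shape[0]
    logp = z - np.log(e.sum(axis=1, keepdims=True))
    loss = -float(np.mean(logp[np.arange(n), labels]))
    grad = probs.copy()
    grad[np.arange(n), labels] -= 1.0
    return loss, (grad / n).astype(DTYPE), probs


# ---------------------------------------------------------------------------
# Optimiser
# ---------------------------------------------------------------------------

class Adam:
    def __init__(self, params: list[Param], lr: float = 2e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        bc1 = 1 - b1 ** self.t
        bc2 = 1 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad * p.grad
            p.value -= (self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)).astype(DTYPE)
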