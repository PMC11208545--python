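"""Neural layers on the autodiff core: linear, conv, norms, attention, Adam.

All parameter initialization draws from a caller-supplied
``numpy.random.Generator`` so every model build is seed-reproducible.
Sequence tensors are laid out (batch, length, channels).
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, concat, conv1d, maxpool1d

__all__ = [
    "Module", "Linear", "Conv1d", "MaxPool1d", "LayerNorm", "BatchNorm1d",
    "MultiHeadAttention", "Dropout", "softmax", "sinusoidal_encoding",
    "mse_loss", "bce_with_logits", "Adam",
]


class Module:
    """Minimal parameter container; children discovered via attributes."""

    def parameters(self):
        params = []
        for name in sorted(vars(self)):
            v = getattr(self, name)
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Tensor) and item.requires_grad:
                        params.append(item)
        return params

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def state_arrays(self):
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays):
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError(f"expected {len(params)} arrays, got {len(arrays)}")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError(f"shape mismatch {p.data.shape} vs {a.shape}")
            p.data = np.asarray(a, dtype=np.float32)


def _glorot(rng: np.random.Generator, shape, fan_in, fan_out) -> np.ndarray:
    lim = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-lim, lim, size=shape).astype(np.float32)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.w = Tensor(_glorot(rng, (n_in, n_out), n_in, n_out), requires_grad=True)
        self.b = Tensor(np.zeros(n_out, dtype=np.float32), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.w + self.b


class Conv1d(Module):
    """Same-padded 1-D convolution, (B, L, C_in) -> (B, L, C_out)."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        self.kernel = kernel
        self.w = Tensor(
            _glorot(rng, (kernel, c_in, c_out), kernel * c_in, kernel * c_out),
            requires_grad=True,
        )
        self.b = Tensor(np.zeros(c_out, dtype=np.float32), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return conv1d(x, self.w, self.b)


class MaxPool1d(Module):
    def __init__(self, kernel: int):
        self.kernel = kernel

    def __call__(self, x: Tensor) -> Tensor:
        return maxpool1d(x, self.kernel)


class LayerNorm(Module):
    def __init__(self, width: int, eps: float = 1e-5):
        self.g = Tensor(np.ones(width, dtype=np.float32), requires_grad=True)
        self.b = Tensor(np.zeros(width, dtype=np.float32), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc**2).mean(axis=-1, keepdims=True)
        return xc / ((var + self.eps).sqrt()) * self.g + self.b


class BatchNorm1d(Module):
    """Normalization over batch and length axes with running statistics."""

    def __init__(self, width: int, eps: float = 1e-5, momentum: float = 0.1):
        self.g = Tensor(np.ones(width, dtype=np.float32), requires_grad=True)
        self.b = Tensor(np.zeros(width, dtype=np.float32), requires_grad=True)
        self.eps = eps
        self.momentum = momentum
        self.running_mean = np.zeros(width, dtype=np.float32)
        self.running_var = np.ones(width, dtype=np.float32)

    def __call__(self, x: Tensor, train: bool = True) -> Tensor:
        if train:
            mu = x.mean(axis=(0, 1), keepdims=True)
            xc = x - mu
            var = (xc**2).mean(axis=(0, 1), keepdims=True)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu.data.ravel()
            self.running_var = (1 - m) * self.running_var + m * var.data.ravel()
            return xc / ((var + self.eps).sqrt()) * self.g + self.b
        xc = x - Tensor(self.running_mean)
        return xc / Tensor(np.sqrt(self.running_var + self.eps)) * self.g + self.b


def softmax(x: Tensor) -> Tensor:
    z = x - Tensor(x.max_lastaxis_detached())
    e = z.exp()
    return e / e.sum(axis=-1, keepdims=True)


class MultiHeadAttention(Module):
    """Standard scaled dot-product self-attention, (B, L, W) -> (B, L, W)."""

    def __init__(self, width: int, n_heads: int, rng: np.random.Generator):
        if width % n_heads:
            raise ValueError(f"width {width} not divisible by {n_heads} heads")
        self.n_heads = n_heads
        self.d_head = width // n_heads
        self.wq = Linear(width, width, rng)
        self.wk = Linear(width, width, rng)
        self.wv = Linear(width, width, rng)
        self.wo = Linear(width, width, rng)

    def __call__(self, x: Tensor) -> Tensor:
        B, L, W = x.shape

        def split(t):
            return t.reshape(B, L, self.n_heads, self.d_head).swapaxes(1, 2)

        q, k, v = split(self.wq(x)), split(self.wk(x)), split(self.wv(x))
        scores = (q @ k.swapaxes(-1, -2)) * (1.0 / np.sqrt(self.d_head))
        out = softmax(scores) @ v  # (B, H, L, D)
        out = out.swapaxes(1, 2).reshape(B, L, W)
        return self.wo(out)


class Dropout(Module):
    def __init__(self, rate: float):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must lie in [0, 1)")
        self.rate = rate

    def __call__(self, x: Tensor, rng: np.random.Generator | None = None,
                 train: bool = False) -> Tensor:
        if not train or self.rate == 0.0 or rng is None:
            return x
        keep = 1.0 - self.rate
        mask = (rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * Tensor(mask)


def sinusoidal_encoding(seq_len: int, width: int) -> np.ndarray:
    """Deterministic sin/cos positional encoding, values in [-1, 1]."""
    if seq_len < 1 or width < 1:
        raise ValueError("seq_len and width must be >= 1")
    pos = np.arange(seq_len, dtype=np.float64)[:, None]
    i = np.arange(width, dtype=np.float64)[None, :]
    angle = pos / np.power(10000.0, (2 * (i // 2)) / width)
    enc = np.where(i % 2 == 0, np.sin(angle), np.cos(angle))
    return enc.astype(np.float32)


def mse_loss(pred: Tensor, target: Tensor) -> Tensor:
    return ((pred - target) ** 2).mean()


def bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Numerically stable binary cross-entropy: mean(softplus(z) - z*y)."""
    y = Tensor(np.asarray(targets, dtype=np.float32))
    return (logits.softplus() - logits * y).mean()


class Adam:
    """Adam with per-parameter first/second moment state (serializable)."""

    def __init__(self, params, lr: float = 1e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * g
            self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * g * g
            mhat = self.m[i] / b1t
            vhat = self.v[i] / b2t
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def state(self) -> dict:
        return {"t": self.t, "m": self.m, "v": self.v}

    def load_state(self, state: dict):
        self.t = int(state["t"])
        self.m = [np.asarray(a, dtype=np.float32) for a in state["m"]]
        self.v = [np.asarray(a, dtype=np.float32) for a in state["v"]]
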