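"""Compact reverse-mode automatic differentiation on NumPy arrays.

Float32 tensors with a dynamically built tape; primitives cover what the
transformer blocks and the 1-D residual network need: broadcasting
arithmetic, batched matmul, reductions, shape ops, pointwise nonlinearities,
and same-padded 1-D convolution / max pooling (implemented im2col-style so
the heavy lifting is BLAS matmul).  Gradients are only propagated through
subgraphs that reach a ``requires_grad`` leaf, so inference-mode forwards
build no tape.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "conv1d", "maxpool1d", "no_grad"]

_GRAD_ENABLED = [True]


class no_grad:
    """Context manager suppressing tape construction (inference mode)."""

    def __enter__(self):
        self._prev = _GRAD_ENABLED[0]
        _GRAD_ENABLED[0] = False
        return self

    def __exit__(self, *exc):
        _GRAD_ENABLED[0] = self._prev
        return False


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


def _as_tensor(x) -> "Tensor":
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float32))


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "needs_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = None
        self.requires_grad = requires_grad
        self.needs_grad = requires_grad
        self._parents = ()
        self._backward = None

    # -- graph plumbing ----------------------------------------------------
    @staticmethod
    def _op(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if _GRAD_ENABLED[0] and any(p.needs_grad for p in parents):
            out.needs_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    def backward(self, grad=None) -> None:
        topo, seen = [], set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = (np.ones_like(self.data) if grad is None
                     else np.asarray(grad, dtype=np.float32))
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        other = _as_tensor(other)

        def bw(g, a=self, b=other):
            if a.needs_grad:
                a._accum(_unbroadcast(g, a.data.shape))
            if b.needs_grad:
                b._accum(_unbroadcast(g, b.data.shape))

        return Tensor._op(self.data + other.data, (self, other), bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g, a=self):
            if a.needs_grad:
                a._accum(-g)

        return Tensor._op(-self.data, (self,), bw)

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __mul__(self, other):
        other = _as_tensor(other)

        def bw(g, a=self, b=other):
            if a.needs_grad:
                a._accum(_unbroadcast(g * b.data, a.data.shape))
            if b.needs_grad:
                b._accum(_unbroadcast(g * a.data, b.data.shape))

        return Tensor._op(self.data * other.data, (self, other), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _as_tensor(other)

        def bw(g, a=self, b=other):
            if a.needs_grad:
                a._accum(_unbroadcast(g / b.data, a.data.shape))
            if b.needs_grad:
                b._accum(_unbroadcast(-g * a.data / (b.data**2), b.data.shape))

        return Tensor._op(self.data / other.data, (self, other), bw)

    def __pow__(self, p: float):
        def bw(g, a=self):
            if a.needs_grad:
                a._accum(g * p * a.data ** (p - 1))

        return Tensor._op(self.data**p, (self,), bw)

    def __matmul__(self, other):
        other = _as_tensor(other)
        out_data = self.data @ other.data

        def bw(g, a=self, b=other):
            if a.needs_grad:
                ga = g @ np.swapaxes(b.data, -1, -2)
                a._accum(_unbroadcast(ga, a.data.shape))
            if b.needs_grad:
                gb = np.swapaxes(a.data, -1, -2) @ g
                b._accum(_unbroadcast(gb, b.data.shape))

        return Tensor._op(out_data, (self, other), bw)

    # -- pointwise ---------------------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def bw(g, a=self, o=out_data):
            if a.needs_grad:
                a._accum(g * o)

        return Tensor._op(out_data, (self,), bw)

    def log(self):
        def bw(g, a=self):
            if a.needs_grad:
                a._accum(g / a.data)

        return Tensor._op(np.log(self.data), (self,), bw)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def bw(g, a=self, o=out_data):
            if a.needs_grad:
                a._accum(g / (2.0 * o))

        return Tensor._op(out_data, (self,), bw)

    def relu(self):
        mask = self.data > 0

        def bw(g, a=self, m=mask):
            if a.needs_grad:
                a._accum(g * m)

        return Tensor._op(self.data * mask, (self,), bw)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def bw(g, a=self, o=out_data):
            if a.needs_grad:
                a._accum(g * o * (1.0 - o))

        return Tensor._op(out_data, (self,), bw)

    def tanh(self):
        out_data = np.tanh(self.data)

        def bw(g, a=self, o=out_data):
            if a.needs_grad:
                a._accum(g * (1.0 - o**2))

        return Tensor._op(out_data, (self,), bw)

    def softplus(self):
        # numerically stable log(1 + e^x); gradient is sigmoid(x)
        out_data = np.logaddexp(0.0, self.data)

        def bw(g, a=self):
            if a.needs_grad:
                a._accum(g / (1.0 + np.exp(-a.data)))

        return Tensor._op(out_data, (self,), bw)

    # -- reductions & shape ------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bw(g, a=self):
            if not a.needs_grad:
                return
            gg = g
            if axis is not None and not keepdims:
                gg = np.expand_dims(gg, axis)
            a._accum(np.broadcast_to(gg, a.data.shape).astype(np.float32))

        return Tensor._op(out_data, (self,), bw)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else (
            np.prod([self.data.shape[a] for a in np.atleast_1d(axis)])
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        def bw(g, a=self):
            if a.needs_grad:
                a._accum(g.reshape(a.data.shape))

        return Tensor._op(self.data.reshape(*shape), (self,), bw)

    def swapaxes(self, a1: int, a2: int):
        def bw(g, a=self):
            if a.needs_grad:
                a._accum(np.swapaxes(g, a1, a2))

        return Tensor._op(np.swapaxes(self.data, a1, a2), (self,), bw)

    def max_lastaxis_detached(self) -> np.ndarray:
        """Constant max over the last axis (for stable softmax)."""
        return self.data.max(axis=-1, keepdims=True)


def concat(tensors, axis: int = -1) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        parts = np.split(g, splits, axis=axis)
        for t, p in zip(tensors, parts):
            if t.needs_grad:
                t._accum(p)

    return Tensor._op(np.concatenate([t.data for t in tensors], axis=axis),
                      tuple(tensors), bw)


def conv1d(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Same-padded 1-D convolution.

    ``x``: (B, L, C_in); ``w``: (K, C_in, C_out); ``b``: (C_out,).
    Implemented as im2col + matmul; backward scatters window gradients.
    """
    K, cin, cout = w.data.shape
    B, L, _ = x.data.shape
    pl, pr = (K - 1) // 2, K // 2
    xp = np.pad(x.data, ((0, 0), (pl, pr), (0, 0)))
    # (B, L, C_in, K) -> (B, L, K*C_in), k-major to match w.reshape(K*cin, cout)
    cols = np.lib.stride_tricks.sliding_window_view(xp, K, axis=1)
    cols = np.ascontiguousarray(cols.transpose(0, 1, 3, 2)).reshape(B, L, K * cin)
    wm = w.data.reshape(K * cin, cout)
    out_data = cols @ wm + b.data

    def bw(g):
        g2 = g.reshape(B * L, cout)
        if w.needs_grad:
            gw = cols.reshape(B * L, K * cin).T @ g2
            w._accum(gw.reshape(K, cin, cout))
        if b.needs_grad:
            b._accum(g2.sum(axis=0))
        if x.needs_grad:
            gcols = (g2 @ wm.T).reshape(B, L, K, cin)
            gxp = np.zeros_like(xp)
            for k in range(K):
                gxp[:, k : k + L, :] += gcols[:, :, k, :]
            x._accum(gxp[:, pl : pl + L, :])

    return Tensor._op(out_data, (x, w, b), bw)


def maxpool1d(x: Tensor, k: int) -> Tensor:
    """Same-padded max pooling with stride 1 (local smoothing; length kept)."""
    if k == 1:
        return x
    B, L, C = x.data.shape
    pl, pr = (k - 1) // 2, k // 2
    xp = np.pad(x.data, ((0, 0), (pl, pr), (0, 0)), constant_values=-np.inf)
    win = np.lib.stride_tricks.sliding_window_view(xp, k, axis=1)  # (B, L, C, k)
    arg = win.argmax(axis=-1)
    out_data = win.max(axis=-1)

    def bw(g):
        if not x.needs_grad:
            return
        gxp = np.zeros((B, L + pl + pr, C), dtype=np.float32)
        for j in range(k):
            mask = arg == j
            gxp[:, j : j + L, :] += g * mask
        x._accum(gxp[:, pl : pl + L, :])

    return Tensor._op(out_data, (x,), bw)
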