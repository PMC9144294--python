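"""Minimal reverse-mode automatic differentiation over numpy arrays.

A :class:`Tensor` wraps an ``ndarray`` and records the operations applied to
it; :meth:`Tensor.backward` walks the recorded graph in reverse topological
order and accumulates gradients into every tensor created with
``requires_grad=True``.  Only the primitives needed by the gait-speed models
are implemented (elementwise arithmetic with broadcasting, matmul, reductions,
shape ops, ``sin``/``exp``/``log``/``tanh``/``sigmoid``/``relu``/``softplus``,
strided 1-D convolution and transposed convolution).  Everything is computed
in float64, which keeps finite-difference gradient checks meaningful.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "conv1d", "conv_transpose1d"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


def _as_tensor(x) -> "Tensor":
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=float))


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=float)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._backward = None
        self._prev: tuple[Tensor, ...] = ()

    # -- graph bookkeeping -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad or p._prev for p in parents):
            out._prev = tuple(parents)
            out._backward = backward
            out.requires_grad = False  # leaf-ness tracked separately
        return out

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(grad, dtype=float, copy=True)
        else:
            self.grad = self.grad + grad

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if id(p) not in seen:
                    stack.append((p, False))
        self._accum(np.asarray(grad, dtype=float))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        other = _as_tensor(other)
        out_data = self.data + other.data

        def backward(g):
            self._accum(_unbroadcast(g, self.data.shape))
            other._accum(_unbroadcast(g, other.data.shape))

        return self._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            self._accum(-g)

        return self._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __mul__(self, other):
        other = _as_tensor(other)
        out_data = self.data * other.data

        def backward(g):
            self._accum(_unbroadcast(g * other.data, self.data.shape))
            other._accum(_unbroadcast(g * self.data, other.data.shape))

        return self._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _as_tensor(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return _as_tensor(other) * self ** -1.0

    def __pow__(self, p: float):
        out_data = self.data ** p

        def backward(g):
            self._accum(g * p * self.data ** (p - 1.0))

        return self._make(out_data, (self,), backward)

    def __matmul__(self, other):
        other = _as_tensor(other)
        out_data = self.data @ other.data

        def backward(g):
            a, b = self.data, other.data
            if a.ndim == 1 and b.ndim == 1:
                self._accum(g * b)
                other._accum(g * a)
                return
            ga = g @ np.swapaxes(b, -1, -2) if b.ndim > 1 else np.outer(g, b) if a.ndim > 1 else g * b
            gb = np.swapaxes(a, -1, -2) @ g if a.ndim > 1 else np.outer(a, g)
            self._accum(_unbroadcast(ga, a.shape))
            other._accum(_unbroadcast(gb, b.shape))

        return self._make(out_data, (self, other), backward)

    # -- reductions --------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape))
                return
            g_exp = g if keepdims else np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g_exp, self.data.shape))

        return self._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- shape -------------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape
        out_data = self.data.reshape(shape)

        def backward(g):
            self._accum(g.reshape(old))

        return self._make(out_data, (self,), backward)

    def swapaxes(self, a: int, b: int):
        out_data = np.swapaxes(self.data, a, b)

        def backward(g):
            self._accum(np.swapaxes(g, a, b))

        return self._make(out_data, (self,), backward)

    def __getitem__(self, idx):
        out_data = self.data[idx]

        def backward(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accum(full)

        return self._make(out_data, (self,), backward)

    # -- elementwise nonlinearities -----------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            self._accum(g * out_data)

        return self._make(out_data, (self,), backward)

    def log(self):
        out_data = np.log(self.data)

        def backward(g):
            self._accum(g / self.data)

        return self._make(out_data, (self,), backward)

    def sin(self):
        out_data = np.sin(self.data)

        def backward(g):
            self._accum(g * np.cos(self.data))

        return self._make(out_data, (self,), backward)

    def tanh(self):
        out_data = np.tanh(self.data)

        def backward(g):
            self._accum(g * (1.0 - out_data ** 2))

        return self._make(out_data, (self,), backward)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            self._accum(g * out_data * (1.0 - out_data))

        return self._make(out_data, (self,), backward)

    def relu(self):
        mask = self.data > 0
        out_data = np.where(mask, self.data, 0.0)

        def backward(g):
            self._accum(g * mask)

        return self._make(out_data, (self,), backward)

    def softplus(self):
        # numerically stable log(1 + e^x)
        out_data = np.logaddexp(0.0, self.data)

        def backward(g):
            self._accum(g / (1.0 + np.exp(-self.data)))

        return self._make(out_data, (self,), backward)

    def __repr__(self):  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, grad={'set' if self.grad is not None else 'None'})"


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            t._accum(g[tuple(sl)])

    out = Tensor(out_data)
    if any(t.requires_grad or t._prev for t in tensors):
        out._prev = tuple(tensors)
        out._backward = backward
    return out


def conv1d(x: Tensor, w: Tensor, b: Tensor | None, stride: int) -> Tensor:
    """Valid cross-correlation.  x: (B, Cin, T); w: (Cout, Cin, K); out (B, Cout, L)."""
    B, Cin, T = x.data.shape
    Cout, Cin_w, K = w.data.shape
    if Cin != Cin_w:
        raise ValueError(f"channel mismatch: input {Cin}, kernel {Cin_w}")
    if T < K:
        raise ValueError(f"input length {T} shorter than kernel {K}")
    L = (T - K) // stride + 1
    idx = stride * np.arange(L)[:, None] + np.arange(K)[None, :]  # (L, K)
    cols = x.data[:, :, idx]                    # (B, Cin, L, K)
    cols = cols.transpose(0, 2, 1, 3).reshape(B, L, Cin * K)
    w_flat = w.data.reshape(Cout, Cin * K)
    out_data = cols @ w_flat.T                  # (B, L, Cout)
    if b is not None:
        out_data = out_data + b.data
    out_data = out_data.transpose(0, 2, 1)      # (B, Cout, L)

    def backward(g):
        g_blc = g.transpose(0, 2, 1)            # (B, L, Cout)
        gw = np.einsum("blo,blk->ok", g_blc, cols)
        w._accum(gw.reshape(Cout, Cin, K))
        if b is not None:
            b._accum(g_blc.sum(axis=(0, 1)))
        gcols = g_blc @ w_flat                  # (B, L, Cin*K)
        gcols = gcols.reshape(B, L, Cin, K).transpose(0, 2, 1, 3)
        gx = np.zeros((B, Cin, T))
        np.add.at(gx, (slice(None), slice(None), idx), gcols)
        x._accum(gx)

    parents = (x, w) if b is None else (x, w, b)
    out = Tensor(out_data)
    if any(p.requires_grad or p._prev for p in parents):
        out._prev = parents
        out._backward = backward
    return out


def conv_transpose1d(x: Tensor, w: Tensor, b: Tensor | None, stride: int) -> Tensor:
    """Transposed 1-D convolution.  x: (B, Cin, T); w: (Cin, Cout, K); out (B, Cout, (T-1)*stride+K)."""
    B, Cin, T = x.data.shape
    Cin_w, Cout, K = w.data.shape
    if Cin != Cin_w:
        raise ValueError(f"channel mismatch: input {Cin}, kernel {Cin_w}")
    L = (T - 1) * stride + K
    x_blc = x.data.transpose(0, 2, 1)           # (B, T, Cin)
    # contributions: out[:, :, t*stride + k] += x[:, t, :] @ w[:, :, k]
    contrib = np.einsum("btc,cok->btok", x_blc, w.data)   # (B, T, Cout, K)
    out_data = np.zeros((B, Cout, L))
    pos = stride * np.arange(T)[:, None] + np.arange(K)[None, :]  # (T, K)
    np.add.at(out_data.transpose(0, 2, 1).reshape(B, L, Cout), 0, 0)  # no-op keeps shape intent clear
    for k in range(K):
        out_data[:, :, stride * np.arange(T) + k] += contrib[:, :, :, k].transpose(0, 2, 1)
    if b is not None:
        out_data = out_data + b.data[None, :, None]

    def backward(g):
        # g: (B, Cout, L)
        g_slices = g[:, :, pos]                 # (B, Cout, T, K)
        gx = np.einsum("botk,cok->bct", g_slices, w.data)
        x._accum(gx)
        gw = np.einsum("botk,bct->cok", g_slices, x.data)
        w._accum(gw)
        if b is not None:
            b._accum(g.sum(axis=(0, 2)))

    parents = (x, w) if b is None else (x, w, b)
    out = Tensor(out_data)
    if any(p.requires_grad or p._prev for p in parents):
        out._prev = parents
        out._backward = backward
    return out
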