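"""Minimal reverse-mode automatic differentiation over numpy arrays.

A :class:`Tensor` wraps an ndarray and remembers how it was produced; calling
``backward()`` on a scalar loss runs the tape in reverse topological order and
accumulates gradients into every reachable tensor with ``requires_grad``.
Only the operations the network needs are provided; each op's backward is a
closure returning one gradient per parent (``None`` for non-differentiable
parents such as index arrays).

Convolutions are expressed as sums of shifted slices rather than im2col
gathers, and scatter-adds (for point gathers) use a sort/reduceat kernel, so
no Python-level loops appear on hot paths.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor", "add", "sub", "mul", "matmul", "relu", "reshape", "concat",
    "getitem", "gather", "max_", "sum_", "mean_", "power", "conv1d",
    "softmax_cross_entropy", "softmax",
]


class Tensor:
    __slots__ = ("data", "grad", "parents", "_backward", "requires_grad")

    def __init__(self, data, requires_grad: bool = False,
                 parents: tuple = (), backward=None):
        self.data = data if isinstance(data, np.ndarray) else np.asarray(data)
        self.requires_grad = requires_grad or any(
            p.requires_grad for p in parents)
        self.parents = parents if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None
        self.grad = None

    # -- introspection -----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- graph execution ---------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        order: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: graphs are deep
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node.parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = grad
        for node in reversed(order):
            if node._backward is None or node.grad is None:
                continue
            for parent, g in zip(node.parents, node._backward(node.grad)):
                if g is None or not parent.requires_grad:
                    continue
                g = np.asarray(g, dtype=parent.data.dtype)
                parent.grad = g if parent.grad is None else parent.grad + g

    def zero_grad(self) -> None:
        self.grad = None

    # -- operator sugar ----------------------------------------------------
    def __add__(self, other):
        return add(self, _as_tensor(other))

    def __radd__(self, other):
        return add(_as_tensor(other), self)

    def __sub__(self, other):
        return sub(self, _as_tensor(other))

    def __mul__(self, other):
        return mul(self, _as_tensor(other))

    def __rmul__(self, other):
        return mul(_as_tensor(other), self)

    def __matmul__(self, other):
        return matmul(self, _as_tensor(other))

    def __getitem__(self, key):
        return getitem(self, key)

    def reshape(self, *shape):
        return reshape(self, shape if len(shape) > 1 else shape[0])


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g.reshape(shape)


# -- elementwise -----------------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data + b.data

    def bw(g):
        return (_unbroadcast(g, a.data.shape), _unbroadcast(g, b.data.shape))

    return Tensor(out_data, parents=(a, b), backward=bw)


def sub(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data - b.data

    def bw(g):
        return (_unbroadcast(g, a.data.shape), _unbroadcast(-g, b.data.shape))

    return Tensor(out_data, parents=(a, b), backward=bw)


def mul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data * b.data

    def bw(g):
        return (_unbroadcast(g * b.data, a.data.shape),
                _unbroadcast(g * a.data, b.data.shape))

    return Tensor(out_data, parents=(a, b), backward=bw)


def power(a: Tensor, exponent: float) -> Tensor:
    out_data = a.data ** exponent

    def bw(g):
        return (g * exponent * a.data ** (exponent - 1.0),)

    return Tensor(out_data, parents=(a,), backward=bw)


def relu(a: Tensor) -> Tensor:
    mask = a.data > 0
    out_data = a.data * mask

    def bw(g):
        return (g * mask,)

    return Tensor(out_data, parents=(a,), backward=bw)


# -- linear algebra --------------------------------------------------------

def matmul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data @ b.data

    def bw(g):
        bt = np.swapaxes(b.data, -1, -2)
        at = np.swapaxes(a.data, -1, -2)
        ga = _unbroadcast(g @ bt, a.data.shape)
        gb = _unbroadcast(at @ g, b.data.shape)
        return (ga, gb)

    return Tensor(out_data, parents=(a, b), backward=bw)


# -- shape manipulation ----------------------------------------------------

def reshape(a: Tensor, shape) -> Tensor:
    out_data = a.data.reshape(shape)

    def bw(g):
        return (g.reshape(a.data.shape),)

    return Tensor(out_data, parents=(a,), backward=bw)


def getitem(a: Tensor, key) -> Tensor:
    out_data = a.data[key]

    def bw(g):
        ga = np.zeros_like(a.data)
        ga[key] = g  # basic (slice) indexing only: no duplicate positions
        return (ga,)

    return Tensor(out_data, parents=(a,), backward=bw)


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor(out_data, parents=tuple(tensors), backward=bw)


# -- gathering -------------------------------------------------------------

def _scatter_add_rows(target: np.ndarray, rows: np.ndarray,
                      values: np.ndarray) -> None:
    """target[rows[m]] += values[m] for 2-D targets, via sort + reduceat."""
    order = np.argsort(rows, kind="stable")
    rows_s = rows[order]
    vals_s = values[order]
    starts = np.flatnonzero(np.r_[True, rows_s[1:] != rows_s[:-1]])
    sums = np.add.reduceat(vals_s, starts, axis=0)
    np.add.at(target, rows_s[starts], sums)  # unique rows: no collisions


def gather(x: Tensor, idx: np.ndarray) -> Tensor:
    """Batched point gather along axis 1.

    ``x`` has shape (B, N, C); ``idx`` has shape (B, ...) of integer indices
    into axis 1. Output shape is (B, *idx.shape[1:], C).
    """
    idx = np.asarray(idx)
    B, N, C = x.data.shape
    bidx = np.arange(B).reshape((B,) + (1,) * (idx.ndim - 1))
    out_data = x.data[bidx, idx]

    def bw(g):
        gx = np.zeros((B * N, C), dtype=x.data.dtype)
        lin = (bidx * N + idx).ravel()
        _scatter_add_rows(gx, lin, g.reshape(-1, C))
        return (gx.reshape(B, N, C),)

    return Tensor(out_data, parents=(x,), backward=bw)


# -- reductions ------------------------------------------------------------

def max_(a: Tensor, axis: int, keepdims: bool = False) -> Tensor:
    kept = a.data.max(axis=axis, keepdims=True)
    out_data = kept if keepdims else np.squeeze(kept, axis=axis)
    mask = a.data == kept

    def bw(g):
        if not keepdims:
            g = np.expand_dims(g, axis)
        return (g * mask,)

    return Tensor(out_data, parents=(a,), backward=bw)


def sum_(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def bw(g):
        if axis is not None and not keepdims:
            g = np.expand_dims(g, axis)
        return (np.broadcast_to(g, a.data.shape).copy(),)

    return Tensor(out_data, parents=(a,), backward=bw)


def mean_(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    out_data = a.data.mean(axis=axis, keepdims=keepdims)
    count = a.data.size / out_data.size

    def bw(g):
        if axis is not None and not keepdims:
            g = np.expand_dims(g, axis)
        return (np.broadcast_to(g, a.data.shape) / count,)

    return Tensor(out_data, parents=(a,), backward=bw)


# -- convolution -----------------------------------------------------------

def conv1d(x: Tensor, weight: Tensor, bias: Tensor,
           dilation: int = 1) -> Tensor:
    """Same-padded 1-D convolution along axis 1.

    ``x``: (B, N, C_in); ``weight``: (k, C_in, C_out); ``bias``: (C_out,).
    Odd kernel sizes only (the padding is symmetric).
    """
    k = weight.data.shape[0]
    if k % 2 == 0:
        raise ValueError("conv1d supports odd kernel sizes only")
    B, N, cin = x.data.shape
    pad = dilation * (k - 1) // 2
    xp = np.pad(x.data, ((0, 0), (pad, pad), (0, 0)))
    out_data = np.broadcast_to(bias.data, (B, N, weight.data.shape[2])).copy()
    for t in range(k):
        out_data += xp[:, t * dilation:t * dilation + N, :] @ weight.data[t]

    def bw(g):
        gw = np.empty_like(weight.data)
        gxp = np.zeros_like(xp)
        for t in range(k):
            sl = slice(t * dilation, t * dilation + N)
            gw[t] = np.tensordot(xp[:, sl, :], g, axes=([0, 1], [0, 1]))
            gxp[:, sl, :] += g @ weight.data[t].T
        gx = gxp[:, pad:pad + N, :] if pad else gxp
        gb = g.sum(axis=(0, 1))
        return (gx, gw, gb)

    return Tensor(out_data, parents=(x, weight, bias), backward=bw)


# -- losses ----------------------------------------------------------------

def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean categorical cross-entropy over the batch; labels are int indices."""
    labels = np.asarray(labels)
    n, c = logits.data.shape
    if labels.min(initial=0) < 0 or labels.max(initial=0) >= c:
        raise ValueError("label index out of range")
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    lse = np.log(np.exp(z).sum(axis=1))
    out_data = np.asarray((lse - z[np.arange(n), labels]).mean(),
                          dtype=logits.data.dtype)

    def bw(g):
        p = softmax(logits.data)
        p[np.arange(n), labels] -= 1.0
        return (p * (g / n),)

    return Tensor(out_data, parents=(logits,), backward=bw)
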