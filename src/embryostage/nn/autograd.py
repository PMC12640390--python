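"""Minimal reverse-mode automatic differentiation on numpy arrays.

Just enough machinery for the stage classifiers: dense/conv layers, a
single-layer self-attention encoder, layer norm and weighted
cross-entropy.  Tensors form a DAG of operations; ``Tensor.backward``
walks it in reverse topological order accumulating gradients.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "add",
    "mul",
    "matmul",
    "relu",
    "reshape",
    "transpose",
    "mean",
    "stack",
    "take_token",
    "softmax",
    "layer_norm",
    "conv2d",
    "cross_entropy",
]


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents = tuple(parents)
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; graphs can be deep
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(grad, dtype=np.float64)
        else:
            self.grad = self.grad + grad

    # light operator sugar
    def __add__(self, other):
        return add(self, other)

    def __mul__(self, other):
        return mul(self, other)

    def __matmul__(self, other):
        return matmul(self, other)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` undoing numpy broadcasting."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


def _make(data, parents, backward) -> Tensor:
    requires = any(p.requires_grad for p in parents)
    return Tensor(data, requires, parents if requires else (), backward if requires else None)


def add(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)

    def backward(grad):
        if a.requires_grad:
            a.accumulate(_unbroadcast(grad, a.shape))
        if b.requires_grad:
            b.accumulate(_unbroadcast(grad, b.shape))

    return _make(a.data + b.data, (a, b), backward)


def mul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)

    def backward(grad):
        if a.requires_grad:
            a.accumulate(_unbroadcast(grad * b.data, a.shape))
        if b.requires_grad:
            b.accumulate(_unbroadcast(grad * a.data, b.shape))

    return _make(a.data * b.data, (a, b), backward)


def matmul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)

    def backward(grad):
        if a.requires_grad:
            ga = grad @ np.swapaxes(b.data, -1, -2)
            a.accumulate(_unbroadcast(ga, a.shape))
        if b.requires_grad:
            gb = np.swapaxes(a.data, -1, -2) @ grad
            b.accumulate(_unbroadcast(gb, b.shape))

    return _make(a.data @ b.data, (a, b), backward)


def relu(x: Tensor) -> Tensor:
    x = _as_tensor(x)
    mask = x.data > 0

    def backward(grad):
        if x.requires_grad:
            x.accumulate(grad * mask)

    return _make(x.data * mask, (x,), backward)


def reshape(x: Tensor, shape) -> Tensor:
    x = _as_tensor(x)
    old = x.shape

    def backward(grad):
        if x.requires_grad:
            x.accumulate(grad.reshape(old))

    return _make(x.data.reshape(shape), (x,), backward)


def transpose(x: Tensor, axes) -> Tensor:
    x = _as_tensor(x)
    inverse = np.argsort(axes)

    def backward(grad):
        if x.requires_grad:
            x.accumulate(grad.transpose(inverse))

    return _make(x.data.transpose(axes), (x,), backward)


def mean(x: Tensor, axis) -> Tensor:
    x = _as_tensor(x)
    axis = tuple(np.atleast_1d(axis).tolist())
    denom = float(np.prod([x.shape[a] for a in axis]))

    def backward(grad):
        if x.requires_grad:
            g = np.expand_dims(grad, axis)
            x.accumulate(np.broadcast_to(g, x.shape) / denom)

    return _make(x.data.mean(axis=axis), (x,), backward)


def stack(tensors, axis: int = 1) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]

    def backward(grad):
        for i, t in enumerate(tensors):
            if t.requires_grad:
                t.accumulate(np.take(grad, i, axis=axis))

    return _make(np.stack([t.data for t in tensors], axis=axis), tuple(tensors), backward)


def take_token(x: Tensor, index: int, axis: int = 1) -> Tensor:
    """Select one token from a (batch, tokens, dim) sequence."""
    x = _as_tensor(x)

    def backward(grad):
        if x.requires_grad:
            g = np.zeros(x.shape)
            sl = [slice(None)] * x.data.ndim
            sl[axis] = index
            g[tuple(sl)] = grad
            x.accumulate(g)

    return _make(np.take(x.data, index, axis=axis), (x,), backward)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    x = _as_tensor(x)
    shifted = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    y = e / e.sum(axis=axis, keepdims=True)

    def backward(grad):
        if x.requires_grad:
            dot = (grad * y).sum(axis=axis, keepdims=True)
            x.accumulate(y * (grad - dot))

    return _make(y, (x,), backward)


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Normalise the last axis, then scale and shift."""
    x, gamma, beta = _as_tensor(x), _as_tensor(gamma), _as_tensor(beta)
    mu = x.data.mean(axis=-1, keepdims=True)
    var = x.data.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv

    def backward(grad):
        if gamma.requires_grad:
            gamma.accumulate(_unbroadcast(grad * xhat, gamma.shape))
        if beta.requires_grad:
            beta.accumulate(_unbroadcast(grad, beta.shape))
        if x.requires_grad:
            gx = grad * gamma.data
            m1 = gx.mean(axis=-1, keepdims=True)
            m2 = (gx * xhat).mean(axis=-1, keepdims=True)
            x.accumulate((gx - m1 - xhat * m2) * inv)

    return _make(xhat * gamma.data + beta.data, (x, gamma, beta), backward)


def conv2d(x: Tensor, w: Tensor, b: Tensor, stride: int = 1, padding: int = 0) -> Tensor:
    """2-D convolution via im2col.  x: (B,C,H,W), w: (O,C,kh,kw), b: (O,)."""
    x, w, b = _as_tensor(x), _as_tensor(w), _as_tensor(b)
    bsz, cin, h, width = x.shape
    cout, _, kh, kw = w.shape
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    ho = (h + 2 * padding - kh) // stride + 1
    wo = (width + 2 * padding - kw) // stride + 1
    windows = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    windows = windows[:, :, ::stride, ::stride]  # (B,C,ho,wo,kh,kw)
    cols = windows.transpose(0, 2, 3, 1, 4, 5).reshape(bsz, ho * wo, cin * kh * kw)
    wmat = w.data.reshape(cout, -1)
    out = cols @ wmat.T + b.data
    out = out.reshape(bsz, ho, wo, cout).transpose(0, 3, 1, 2)

    def backward(grad):
        g = grad.transpose(0, 2, 3, 1).reshape(bsz, ho * wo, cout)
        if b.requires_grad:
            b.accumulate(g.sum(axis=(0, 1)))
        if w.requires_grad:
            gw = np.einsum("bno,bnk->ok", g, cols)
            w.accumulate(gw.reshape(w.shape))
        if x.requires_grad:
            gcols = (g @ wmat).reshape(bsz, ho, wo, cin, kh, kw)
            gxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    gxp[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride] += (
                        gcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
                    )
            if padding:
                gxp = gxp[:, :, padding:-padding, padding:-padding]
            x.accumulate(gxp)

    return _make(out, (x, w, b), backward)


def cross_entropy(
    logits: Tensor, targets: np.ndarray, class_weights: np.ndarray | None = None
) -> Tensor:
    """Weighted softmax cross-entropy, averaged with per-sample weights.

    Matches the usual 'mean' reduction for weighted losses:
    ``sum(w_y * ce) / sum(w_y)``, so unit weights give the plain mean.
    """
    logits = _as_tensor(logits)
    targets = np.asarray(targets, dtype=np.int64)
    n, k = logits.shape
    if targets.shape != (n,):
        raise ValueError(f"targets shape {targets.shape} does not match batch size {n}")
    w = np.ones(k) if class_weights is None else np.asarray(class_weights, dtype=np.float64)
    if w.shape != (k,):
        raise ValueError(f"class_weights must have length {k}")
    shifted = logits.data - logits.data.max(axis=1, keepdims=True)
    lse = np.log(np.exp(shifted).sum(axis=1)) + logits.data.max(axis=1)
    ce = lse - logits.data[np.arange(n), targets]
    wy = w[targets]
    denom = wy.sum()
    loss = (wy * ce).sum() / denom

    def backward(grad):
        if logits.requires_grad:
            p = np.exp(shifted)
            p /= p.sum(axis=1, keepdims=True)
            p[np.arange(n), targets] -= 1.0
            logits.accumulate(grad * p * (wy / denom)[:, None])

    return _make(loss, (logits,), backward)
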