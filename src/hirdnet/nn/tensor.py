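"""Reverse-mode automatic differentiation on numpy arrays.

A :class:`Tensor` wraps a float32 ndarray and records the operations applied
to it in a dynamically built computation graph.  Calling :meth:`Tensor.backward`
on a scalar result propagates gradients to every tensor in the graph, so
arbitrary branched architectures (concatenations, additive skips, attention
gates) differentiate correctly.  Gradients are retained on intermediate nodes
as well as leaves, which is what class-activation mapping needs.

Only the operations required by the network are implemented; convolution and
pooling use im2col/col2im so the heavy lifting is a single matmul.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "concat",
    "conv2d",
    "max_pool2d",
    "global_avg_pool",
    "batch_norm",
    "softmax",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (the inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in parents)
        self._parents = tuple(parents)
        self._backward = backward

    # -- basic introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={'set' if self.grad is not None else 'none'})"

    def item(self) -> float:
        return float(self.data)

    # -- graph construction helpers ------------------------------------------
    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def backward(g):
            self._accumulate(_unbroadcast(g, self.data.shape))
            other._accumulate(_unbroadcast(g, other.data.shape))

        out._backward = backward
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))
        out._backward = lambda g: self._accumulate(-g)
        return out

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def backward(g):
            self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        out._backward = backward
        return out

    __rmul__ = __mul__

    def __truediv__(self, scalar: float):
        return self * (1.0 / float(scalar))

    def matmul(self, other: "Tensor") -> "Tensor":
        out = Tensor(self.data @ other.data, parents=(self, other))

        def backward(g):
            self._accumulate(g @ other.data.T)
            other._accumulate(self.data.T @ g)

        out._backward = backward
        return out

    __matmul__ = matmul

    def reshape(self, *shape) -> "Tensor":
        out = Tensor(self.data.reshape(*shape), parents=(self,))
        out._backward = lambda g: self._accumulate(g.reshape(self.data.shape))
        return out

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))

        def backward(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.data.shape).astype(np.float32))

        out._backward = backward
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- pointwise nonlinearities ---------------------------------------------
    def relu(self) -> "Tensor":
        out = Tensor(np.maximum(self.data, 0.0), parents=(self,))
        out._backward = lambda g: self._accumulate(g * (self.data > 0))
        return out

    def relu6(self) -> "Tensor":
        out = Tensor(np.clip(self.data, 0.0, 6.0), parents=(self,))
        out._backward = lambda g: self._accumulate(g * ((self.data > 0) & (self.data < 6)))
        return out

    def hard_swish(self) -> "Tensor":
        """x * relu6(x + 3) / 6 with its exact piecewise derivative."""
        x = self.data
        out = Tensor(x * np.clip(x + 3.0, 0.0, 6.0) / 6.0, parents=(self,))

        def backward(g):
            d = np.where(x <= -3.0, 0.0, np.where(x >= 3.0, 1.0, (2.0 * x + 3.0) / 6.0))
            self._accumulate(g * d.astype(np.float32))

        out._backward = backward
        return out

    def sigmoid(self) -> "Tensor":
        x = self.data
        s = np.where(x >= 0, 1.0 / (1.0 + np.exp(-np.abs(x))),
                     np.exp(-np.abs(x)) / (1.0 + np.exp(-np.abs(x)))).astype(np.float32)
        out = Tensor(s, parents=(self,))
        out._backward = lambda g: self._accumulate(g * s * (1.0 - s))
        return out

    def log(self) -> "Tensor":
        out = Tensor(np.log(self.data), parents=(self,))
        out._backward = lambda g: self._accumulate(g / self.data)
        return out

    def pow_const(self, p: float) -> "Tensor":
        out = Tensor(self.data**p, parents=(self,))
        out._backward = lambda g: self._accumulate(g * p * self.data ** (p - 1.0))
        return out

    def clip_min(self, lo: float) -> "Tensor":
        out = Tensor(np.maximum(self.data, lo), parents=(self,))
        out._backward = lambda g: self._accumulate(g * (self.data > lo))
        return out

    # -- backward pass ---------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=np.float32).reshape(self.data.shape)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


# -- structural operations ------------------------------------------------------


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            idx = [slice(None)] * g.ndim
            idx[axis] = slice(a, b)
            t._accumulate(g[tuple(idx)])

    out._backward = backward
    return out


def _im2col(x: np.ndarray, kh: int, kw: int, sh: int, sw: int, ph: int, pw: int):
    b, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    ho = (h + 2 * ph - kh) // sh + 1
    wo = (w + 2 * pw - kw) // sw + 1
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    win = win[:, :, ::sh, ::sw]  # B, C, Ho, Wo, kh, kw
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(b * ho * wo, c * kh * kw)
    return np.ascontiguousarray(cols), ho, wo


def _col2im(grad_cols, xshape, kh, kw, sh, sw, ph, pw, ho, wo):
    b, c, h, w = xshape
    gx = np.zeros((b, c, h + 2 * ph, w + 2 * pw), dtype=np.float32)
    g6 = grad_cols.reshape(b, ho, wo, c, kh, kw).transpose(0, 3, 4, 5, 1, 2)
    for i in range(kh):
        for j in range(kw):
            gx[:, :, i : i + sh * ho : sh, j : j + sw * wo : sw] += g6[:, :, i, j]
    if ph or pw:
        gx = gx[:, :, ph : ph + h, pw : pw + w]
    return gx


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, stride: int = 1,
           padding: int | tuple[int, int] = 0) -> Tensor:
    """2-D convolution (cross-correlation) over NCHW input.

    ``w`` has shape (C_out, C_in, kh, kw).  ``padding`` may be an int applied
    to both spatial axes or a (ph, pw) pair.
    """
    cout, cin, kh, kw = w.data.shape
    ph, pw = (padding, padding) if isinstance(padding, int) else padding
    sh = sw = stride
    if x.data.shape[1] != cin:
        raise ValueError(f"conv2d: input has {x.data.shape[1]} channels, kernel expects {cin}")
    cols, ho, wo = _im2col(x.data, kh, kw, sh, sw, ph, pw)
    wmat = w.data.reshape(cout, -1)
    out_mat = cols @ wmat.T
    if b is not None:
        out_mat = out_mat + b.data
    bsz = x.data.shape[0]
    out = Tensor(out_mat.reshape(bsz, ho, wo, cout).transpose(0, 3, 1, 2),
                 parents=(x, w) if b is None else (x, w, b))

    def backward(g):
        gm = g.transpose(0, 2, 3, 1).reshape(-1, cout)
        w._accumulate((gm.T @ cols).reshape(w.data.shape))
        if b is not None:
            b._accumulate(gm.sum(axis=0))
        gcols = gm @ wmat
        x._accumulate(_col2im(gcols, x.data.shape, kh, kw, sh, sw, ph, pw, ho, wo))

    out._backward = backward
    return out


def max_pool2d(x: Tensor, kernel: int = 2, stride: int | None = None, padding: int = 0) -> Tensor:
    stride = kernel if stride is None else stride
    kh = kw = kernel
    sh = sw = stride
    b, c, h, w = x.data.shape
    xp = x.data
    if padding:
        xp = np.pad(xp, ((0, 0), (0, 0), (padding, padding), (padding, padding)),
                    constant_values=-np.inf)
    hp, wp = xp.shape[2], xp.shape[3]
    ho = (hp - kh) // sh + 1
    wo = (wp - kw) // sw + 1
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))[:, :, ::sh, ::sw]
    flat = win.reshape(b, c, ho, wo, kh * kw)
    arg = flat.argmax(axis=-1)
    out = Tensor(np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0], parents=(x,))

    def backward(g):
        onehot = np.zeros_like(flat)
        np.put_along_axis(onehot, arg[..., None], g[..., None], axis=-1)
        g6 = onehot.reshape(b, c, ho, wo, kh, kw).transpose(0, 1, 4, 5, 2, 3)
        gx = np.zeros((b, c, hp, wp), dtype=np.float32)
        for i in range(kh):
            for j in range(kw):
                gx[:, :, i : i + sh * ho : sh, j : j + sw * wo : sw] += g6[:, :, i, j]
        if padding:
            gx = gx[:, :, padding : padding + h, padding : padding + w]
        x._accumulate(gx)

    out._backward = backward
    return out


def global_avg_pool(x: Tensor) -> Tensor:
    """Per-channel spatial mean: (B, C, H, W) -> (B, C)."""
    b, c, h, w = x.data.shape
    out = Tensor(x.data.mean(axis=(2, 3)), parents=(x,))

    def backward(g):
        x._accumulate(np.broadcast_to(g[:, :, None, None] / (h * w), x.data.shape).astype(np.float32))

    out._backward = backward
    return out


def batch_norm(x: Tensor, gamma: Tensor, beta: Tensor, train: bool,
               mean: np.ndarray | None = None, var: np.ndarray | None = None,
               eps: float = 1e-3, stats_out: dict | None = None) -> Tensor:
    """Channel-wise batch normalization over NCHW input.

    In training mode the batch moments are used (and reported through
    ``stats_out`` so the caller can maintain running averages); in evaluation
    mode the supplied ``mean``/``var`` are used.
    """
    axes = (0, 2, 3)
    if train:
        mu = x.data.mean(axis=axes)
        var = x.data.var(axis=axes)
        if stats_out is not None:
            stats_out["mean"] = mu
            stats_out["var"] = var
    else:
        if mean is None or var is None:
            raise ValueError("evaluation-mode batch norm needs mean and var")
        mu = mean
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu[None, :, None, None]) * inv[None, :, None, None]
    out = Tensor(gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None],
                 parents=(x, gamma, beta))
    n = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]

    def backward(g):
        gamma._accumulate((g * xhat).sum(axis=axes))
        beta._accumulate(g.sum(axis=axes))
        gs = gamma.data[None, :, None, None] * inv[None, :, None, None]
        if train:
            gmean = g.mean(axis=axes)[None, :, None, None]
            gxhat = (g * xhat).mean(axis=axes)[None, :, None, None]
            x._accumulate(gs * (g - gmean - xhat * gxhat))
        else:
            x._accumulate(gs * g)

    out._backward = backward
    return out


def softmax(x: Tensor, axis: int = 1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=axis, keepdims=True)
    out = Tensor(p, parents=(x,))

    def backward(g):
        dot = (g * p).sum(axis=axis, keepdims=True)
        x._accumulate(p * (g - dot))

    out._backward = backward
    return out
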