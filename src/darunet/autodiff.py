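"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Arrays follow the (batch, height, width, channels) layout everywhere.
Only the operations required by an attention-gated residual U-Net are
provided: broadcast arithmetic, reductions, pointwise nonlinearities,
strided same-padded convolution, stride-2 transposed convolution,
channel concatenation, x2 spatial upsampling and dropout.

Gradients are accumulated by topological-order backward traversal;
every op's backward is exercised against central finite differences in
the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Parameter", "concat"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


def _same_pad(size: int, k: int, s: int) -> tuple[int, int]:
    """'same' padding (TF convention): output = ceil(size/s)."""
    out = -(-size // s)
    total = max((out - 1) * s + k - size, 0)
    return total // 2, total - total // 2


class Tensor:
    """A NumPy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- graph plumbing ------------------------------------------------

    @classmethod
    def _make(cls, data, parents, backward):
        t = cls(data, requires_grad=any(p.requires_grad for p in parents))
        if t.requires_grad:
            t._parents = tuple(parents)
            t._backward = backward
        return t

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def zero_grad(self):
        self.grad = None

    def backward(self, grad: np.ndarray | None = None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS: deep graphs exceed recursion limit
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)
                node._parents = ()
                node._backward = None

    def _accum(self, grad: np.ndarray):
        if not self.requires_grad:
            return
        if self.grad is None:
            self.grad = grad.copy() if grad.base is not None else grad
        else:
            self.grad = self.grad + grad

    # -- arithmetic ----------------------------------------------------

    @staticmethod
    def _wrap(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._wrap(other)
        out_data = self.data + other.data

        def backward(g):
            self._accum(_unbroadcast(g, self.data.shape))
            other._accum(_unbroadcast(g, other.data.shape))

        return Tensor._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __mul__(self, other):
        other = self._wrap(other)
        out_data = self.data * other.data
        a_data, b_data = self.data, other.data

        def backward(g):
            self._accum(_unbroadcast(g * b_data, a_data.shape))
            other._accum(_unbroadcast(g * a_data, b_data.shape))

        return Tensor._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __neg__(self):
        def backward(g):
            self._accum(-g)

        return Tensor._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __truediv__(self, other):
        other = self._wrap(other)
        inv = 1.0 / other.data
        out_data = self.data * inv
        a_data = self.data

        def backward(g):
            self._accum(_unbroadcast(g * inv, a_data.shape))
            other._accum(_unbroadcast(-g * a_data * inv * inv, other.data.shape))

        return Tensor._make(out_data, (self, other), backward)

    def __pow__(self, exponent: float):
        out_data = self.data ** exponent
        x = self.data

        def backward(g):
            self._accum(g * exponent * x ** (exponent - 1))

        return Tensor._make(out_data, (self,), backward)

    # -- reductions ----------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)
        shape = self.data.shape

        def backward(g):
            if axis is None:
                self._accum(np.broadcast_to(g, shape))
            else:
                if not keepdims:
                    g = np.expand_dims(g, axis)
                self._accum(np.broadcast_to(g, shape))

        return Tensor._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # -- pointwise nonlinearities -------------------------------------

    def relu(self):
        mask = self.data > 0

        def backward(g):
            self._accum(g * mask)

        return Tensor._make(self.data * mask, (self,), backward)

    def leaky_relu(self, slope: float = 0.2):
        factor = np.where(self.data > 0, 1.0, slope)

        def backward(g):
            self._accum(g * factor)

        return Tensor._make(self.data * factor, (self,), backward)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            self._accum(g * out_data * (1.0 - out_data))

        return Tensor._make(out_data, (self,), backward)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def backward(g):
            self._accum(g * 0.5 / out_data)

        return Tensor._make(out_data, (self,), backward)

    # -- structured ops ------------------------------------------------

    def conv2d(self, weight: "Tensor", bias: "Tensor | None" = None,
               stride: int = 1) -> "Tensor":
        """Same-padded 2-D correlation, NHWC input, (kh,kw,cin,cout) weight."""
        x, w = self.data, weight.data
        n, h, wd, cin = x.shape
        kh, kw, wcin, cout = w.shape
        if cin != wcin:
            raise ValueError(f"conv2d channel mismatch: input {cin}, weight {wcin}")
        pt, pb = _same_pad(h, kh, stride)
        pl, pr = _same_pad(wd, kw, stride)
        xp = np.pad(x, ((0, 0), (pt, pb), (pl, pr), (0, 0)))
        win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(1, 2))
        cols = win[:, ::stride, ::stride]        # (n, ho, wo, cin, kh, kw)
        out = np.tensordot(cols, w, axes=([4, 5, 3], [0, 1, 2]))
        if bias is not None:
            out = out + bias.data
        ho, wo = out.shape[1], out.shape[2]
        parents = (self, weight) if bias is None else (self, weight, bias)

        def backward(g):
            if weight.requires_grad:
                gw = np.tensordot(cols, g, axes=([0, 1, 2], [0, 1, 2]))
                # cols axes (cin, kh, kw) -> weight layout (kh, kw, cin, cout)
                weight._accum(gw.transpose(1, 2, 0, 3))
            if bias is not None and bias.requires_grad:
                bias._accum(g.sum(axis=(0, 1, 2)))
            if self.requires_grad:
                gxp = np.zeros_like(xp)
                for i in range(kh):
                    for j in range(kw):
                        gxp[:, i:i + stride * ho:stride,
                            j:j + stride * wo:stride] += g @ w[i, j].T
                self._accum(gxp[:, pt:pt + h, pl:pl + wd])

        return Tensor._make(out, parents, backward)

    def conv_transpose2d(self, weight: "Tensor", bias: "Tensor | None" = None,
                         stride: int = 2) -> "Tensor":
        """Same-padded transposed convolution: spatial dims scaled by `stride`.

        Weight layout (kh, kw, cin, cout) with cin = input channels.
        Implemented as the adjoint of the matching strided convolution.
        """
        x, w = self.data, weight.data
        n, h, wd, cin = x.shape
        kh, kw, wcin, cout = w.shape
        if cin != wcin:
            raise ValueError(
                f"conv_transpose2d channel mismatch: input {cin}, weight {wcin}")
        oh, ow = h * stride, wd * stride
        pt, pb = _same_pad(oh, kh, stride)
        pl, pr = _same_pad(ow, kw, stride)
        op = np.zeros((n, oh + pt + pb, ow + pl + pr, cout), dtype=x.dtype)
        for i in range(kh):
            for j in range(kw):
                op[:, i:i + stride * h:stride, j:j + stride * wd:stride] += x @ w[i, j]
        out = op[:, pt:pt + oh, pl:pl + ow]
        if bias is not None:
            out = out + bias.data
        parents = (self, weight) if bias is None else (self, weight, bias)

        def backward(g):
            gp = np.pad(g, ((0, 0), (pt, pb), (pl, pr), (0, 0)))
            if self.requires_grad:
                win = np.lib.stride_tricks.sliding_window_view(
                    gp, (kh, kw), axis=(1, 2))[:, ::stride, ::stride]
                self._accum(np.tensordot(win, w, axes=([4, 5, 3], [0, 1, 3])))
            if weight.requires_grad:
                gw = np.empty_like(w)
                for i in range(kh):
                    for j in range(kw):
                        sub = gp[:, i:i + stride * h:stride, j:j + stride * wd:stride]
                        gw[i, j] = np.tensordot(x, sub, axes=([0, 1, 2], [0, 1, 2]))
                weight._accum(gw)
            if bias is not None and bias.requires_grad:
                bias._accum(g.sum(axis=(0, 1, 2)))

        return Tensor._make(out, parents, backward)

    def upsample2x(self, mode: str = "bilinear") -> "Tensor":
        """Double spatial dimensions (NHWC)."""
        if mode == "nearest":
            out_data = self.data.repeat(2, axis=1).repeat(2, axis=2)

            def backward(g):
                n, oh, ow, c = g.shape
                self._accum(
                    g.reshape(n, oh // 2, 2, ow // 2, 2, c).sum(axis=(2, 4)))

            return Tensor._make(out_data, (self,), backward)
        if mode != "bilinear":
            raise ValueError(f"unknown upsampling mode {mode!r}")
        n, h, w, c = self.data.shape
        idx_h, wgt_h = _bilinear_axis(h)
        idx_w, wgt_w = _bilinear_axis(w)
        # gather along rows then columns; weights broadcast over the rest
        rows = (self.data[:, idx_h[:, 0]] * wgt_h[None, :, 0, None, None]
                + self.data[:, idx_h[:, 1]] * wgt_h[None, :, 1, None, None])
        out_data = (rows[:, :, idx_w[:, 0]] * wgt_w[None, None, :, 0, None]
                    + rows[:, :, idx_w[:, 1]] * wgt_w[None, None, :, 1, None])

        def backward(g):
            g_rows = np.zeros((n, h, 2 * w, c))
            np.add.at(g_rows, (slice(None), idx_h[:, 0]),
                      g * wgt_h[None, :, 0, None, None])
            np.add.at(g_rows, (slice(None), idx_h[:, 1]),
                      g * wgt_h[None, :, 1, None, None])
            # transpose so np.add.at indexes the leading axis contiguously
            g_rows = g_rows.transpose(0, 2, 1, 3)  # (n, 2w, h, c)
            gx = np.zeros((n, w, h, c))
            np.add.at(gx, (slice(None), idx_w[:, 0]),
                      g_rows * wgt_w[None, :, 0, None, None])
            np.add.at(gx, (slice(None), idx_w[:, 1]),
                      g_rows * wgt_w[None, :, 1, None, None])
            self._accum(gx.transpose(0, 2, 1, 3))

        return Tensor._make(out_data, (self,), backward)

    def dropout(self, rate: float, rng: np.random.Generator) -> "Tensor":
        """Inverted dropout; call only in training mode."""
        if rate <= 0:
            return self
        keep = 1.0 - rate
        mask = (rng.random(self.data.shape) < keep) / keep

        def backward(g):
            self._accum(g * mask)

        return Tensor._make(self.data * mask, (self,), backward)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"


def _bilinear_axis(size: int) -> tuple[np.ndarray, np.ndarray]:
    """Source indices and weights for x2 bilinear upsampling (half-pixel centers)."""
    src = (np.arange(2 * size) + 0.5) / 2.0 - 0.5
    lo = np.clip(np.floor(src).astype(int), 0, size - 1)
    hi = np.clip(lo + 1, 0, size - 1)
    frac = np.clip(src - np.floor(src), 0.0, 1.0)
    frac[src < 0] = 0.0
    idx = np.stack([lo, hi], axis=1)
    wgt = np.stack([1.0 - frac, frac], axis=1)
    return idx, wgt


class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    """Concatenate tensors along `axis` (default: channel axis)."""
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t._accum(piece)

    return Tensor._make(out_data, tuple(tensors), backward)
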