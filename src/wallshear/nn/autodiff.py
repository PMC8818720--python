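"""Minimal reverse-mode automatic differentiation over numpy arrays.

Just enough machinery to express and train the convolutional estimator:
broadcasting elementwise arithmetic, matmul, reductions, reshapes, 2D
padding with periodic/replicate/zero modes, valid-window convolution via
im2col, 2x2 max pooling, and bilinear resizing. Gradients are accumulated by
topologically-ordered backward passes from a scalar loss.

Arrays use the (batch, height, width, channels) layout; height is the
circumferential (periodic) flatmap axis.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (adjoint of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """Array node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")
    __array_priority__ = 100  # numpy defers binary ops to Tensor

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=float)
        self.grad = None
        self.requires_grad = requires_grad
        self._parents: tuple = ()
        self._backward = None

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- graph plumbing -----------------------------------------------------

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        out.requires_grad = any(p.requires_grad for p in parents)
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def backward(self, grad=None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.asarray(grad, dtype=float)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, grad: np.ndarray) -> None:
        if not self.requires_grad:
            return
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    def zero_grad(self) -> None:
        self.grad = None

    # -- elementwise --------------------------------------------------------

    def __add__(self, other):
        other = self._lift(other)
        out = self._make(self.data + other.data, (self, other), None)
        if out.requires_grad:
            def backward(g):
                self._accum(_unbroadcast(g, self.data.shape))
                other._accum(_unbroadcast(g, other.data.shape))
            out._backward = backward
        return out

    __radd__ = __add__

    def __neg__(self):
        out = self._make(-self.data, (self,), None)
        if out.requires_grad:
            out._backward = lambda g: self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = self._make(self.data * other.data, (self, other), None)
        if out.requires_grad:
            def backward(g):
                self._accum(_unbroadcast(g * other.data, self.data.shape))
                other._accum(_unbroadcast(g * self.data, other.data.shape))
            out._backward = backward
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        out = self._make(self.data / other.data, (self, other), None)
        if out.requires_grad:
            def backward(g):
                self._accum(_unbroadcast(g / other.data, self.data.shape))
                other._accum(
                    _unbroadcast(-g * self.data / other.data**2, other.data.shape)
                )
            out._backward = backward
        return out

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def __pow__(self, exponent: float):
        out = self._make(self.data**exponent, (self,), None)
        if out.requires_grad:
            out._backward = lambda g: self._accum(
                g * exponent * self.data ** (exponent - 1)
            )
        return out

    def sqrt(self):
        out = self._make(np.sqrt(self.data), (self,), None)
        if out.requires_grad:
            out._backward = lambda g: self._accum(g * 0.5 / np.sqrt(self.data))
        return out

    def abs(self):
        out = self._make(np.abs(self.data), (self,), None)
        if out.requires_grad:
            sign = np.sign(self.data)
            out._backward = lambda g: self._accum(g * sign)
        return out

    def relu(self):
        mask = self.data > 0
        out = self._make(self.data * mask, (self,), None)
        if out.requires_grad:
            out._backward = lambda g: self._accum(g * mask)
        return out

    # -- linear algebra / reductions ----------------------------------------

    def matmul(self, other):
        other = self._lift(other)
        out = self._make(self.data @ other.data, (self, other), None)
        if out.requires_grad:
            def backward(g):
                self._accum(g @ other.data.T)
                other._accum(self.data.T @ g)
            out._backward = backward
        return out

    __matmul__ = matmul

    def sum(self, axis=None, keepdims: bool = False):
        out = self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), None)
        if out.requires_grad:
            def backward(g):
                if axis is not None and not keepdims:
                    axes = axis if isinstance(axis, tuple) else (axis,)
                    g = np.expand_dims(g, axes)
                self._accum(np.broadcast_to(g, self.data.shape).copy())
            out._backward = backward
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape
        out = self._make(self.data.reshape(shape), (self,), None)
        if out.requires_grad:
            out._backward = lambda g: self._accum(g.reshape(old))
        return out

    def transpose(self, axes):
        inv = np.argsort(axes)
        out = self._make(self.data.transpose(axes), (self,), None)
        if out.requires_grad:
            out._backward = lambda g: self._accum(g.transpose(inv))
        return out

    # -- structural ops ------------------------------------------------------

    @staticmethod
    def concat(tensors, axis: int = -1):
        tensors = [Tensor._lift(t) for t in tensors]
        data = np.concatenate([t.data for t in tensors], axis=axis)
        out = tensors[0]._make(data, tuple(tensors), None)
        if out.requires_grad:
            sizes = [t.data.shape[axis] for t in tensors]
            splits = np.cumsum(sizes)[:-1]
            def backward(g):
                for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
                    t._accum(piece)
            out._backward = backward
        return out

    def pad2d(self, pad: int, row_mode: str = "periodic", col_mode: str = "replicate"):
        """Pad the H and W axes of a (B, H, W, C) tensor.

        Row modes: periodic (wrap, for the circumferential axis) or zero.
        Column modes: replicate (edge, for the open longitudinal axis) or zero.
        """
        b, h, w, c = self.data.shape
        if pad >= h:
            raise ValueError(f"padding {pad} must be smaller than height {h}")
        if row_mode == "periodic":
            rows = np.concatenate(
                [np.arange(h - pad, h), np.arange(h), np.arange(pad)]
            )
        elif row_mode == "zero":
            rows = None
        else:
            raise ValueError(f"unknown row mode {row_mode!r}")
        if col_mode == "replicate":
            cols = np.concatenate(
                [np.zeros(pad, dtype=int), np.arange(w), np.full(pad, w - 1)]
            )
        elif col_mode == "zero":
            cols = None
        else:
            raise ValueError(f"unknown col mode {col_mode!r}")

        data = self.data
        if rows is not None:
            data = data[:, rows]
        else:
            z = np.zeros((b, pad, data.shape[2], c))
            data = np.concatenate([z, data, z], axis=1)
        if cols is not None:
            data = data[:, :, cols]
        else:
            z = np.zeros((b, data.shape[1], pad, c))
            data = np.concatenate([z, data, z], axis=2)

        out = self._make(data, (self,), None)
        if out.requires_grad:
            def backward(g):
                gi = np.zeros_like(self.data)
                # adjoint of column indexing
                if cols is not None:
                    gc = np.zeros((b, g.shape[1], w, c))
                    np.add.at(gc, (slice(None), slice(None), cols), g)
                else:
                    gc = g[:, :, pad : pad + w]
                if rows is not None:
                    np.add.at(gi, (slice(None), rows), gc)
                else:
                    gi += gc[:, pad : pad + h]
                self._accum(gi)
            out._backward = backward
        return out

    def conv2d_valid(self, weight: "Tensor", bias: "Tensor | None" = None):
        """Valid-mode 2D convolution (cross-correlation).

        self: (B, H, W, Cin); weight: (kh, kw, Cin, Cout); bias: (Cout,).
        Output: (B, H - kh + 1, W - kw + 1, Cout).
        """
        weight = self._lift(weight)
        b, h, w, cin = self.data.shape
        kh, kw, cin2, cout = weight.data.shape
        if cin != cin2:
            raise ValueError(f"channel mismatch: input {cin} vs weight {cin2}")
        oh, ow = h - kh + 1, w - kw + 1
        windows = sliding_window_view(self.data, (kh, kw), axis=(1, 2))
        # windows: (B, oh, ow, Cin, kh, kw) -> cols (B*oh*ow, kh*kw*Cin)
        cols = windows.transpose(0, 1, 2, 4, 5, 3).reshape(b * oh * ow, kh * kw * cin)
        wmat = weight.data.reshape(kh * kw * cin, cout)
        out_data = (cols @ wmat).reshape(b, oh, ow, cout)
        parents = [self, weight]
        if bias is not None:
            bias = self._lift(bias)
            out_data = out_data + bias.data
            parents.append(bias)
        out = self._make(out_data, tuple(parents), None)
        if out.requires_grad:
            def backward(g):
                gmat = g.reshape(b * oh * ow, cout)
                if weight.requires_grad:
                    gw = cols.T @ gmat
                    weight._accum(gw.reshape(kh, kw, cin, cout))
                if bias is not None and bias.requires_grad:
                    bias._accum(gmat.sum(axis=0))
                if self.requires_grad:
                    gcols = (gmat @ wmat.T).reshape(b, oh, ow, kh, kw, cin)
                    gx = np.zeros_like(self.data)
                    for i in range(kh):
                        for j in range(kw):
                            gx[:, i : i + oh, j : j + ow, :] += gcols[:, :, :, i, j, :]
                    self._accum(gx)
            out._backward = backward
        return out

    def box_mean_valid(self, win: int):
        """Valid-mode uniform (box) filter over the last two axes of a
        (B, H, W) tensor via integral images; adjoint is a zero-padded box
        filter, so backward is O(N) as well."""
        b, h, w = self.data.shape
        if h < win or w < win:
            raise ValueError("image smaller than the filter window")
        out_data = _sliding_sum2d(self.data, win) / (win * win)
        out = self._make(out_data, (self,), None)
        if out.requires_grad:
            def backward(g):
                padded = np.zeros((b, h + win - 1, w + win - 1))
                padded[:, win - 1 : win - 1 + g.shape[1], win - 1 : win - 1 + g.shape[2]] = g
                self._accum(_sliding_sum2d(padded, win) / (win * win))
            out._backward = backward
        return out

    def maxpool2x(self):
        """2x2 max pooling on (B, H, W, C); H and W must be even."""
        b, h, w, c = self.data.shape
        if h % 2 or w % 2:
            raise ValueError("maxpool2x needs even spatial dims")
        blocks = self.data.reshape(b, h // 2, 2, w // 2, 2, c)
        out_data = blocks.max(axis=(2, 4))
        out = self._make(out_data, (self,), None)
        if out.requires_grad:
            flat = blocks.transpose(0, 1, 3, 5, 2, 4).reshape(b, h // 2, w // 2, c, 4)
            arg = flat.argmax(axis=-1)
            onehot = np.eye(4)[arg]  # (b, h/2, w/2, c, 4)
            def backward(g):
                gb = g[..., None] * onehot  # (b, h/2, w/2, c, 4)
                gb = gb.reshape(b, h // 2, w // 2, c, 2, 2).transpose(0, 1, 4, 2, 5, 3)
                self._accum(gb.reshape(b, h, w, c))
            out._backward = backward
        return out

    def resize_bilinear(self, out_h: int, out_w: int):
        """Bilinear resize of (B, H, W, C) via separable interpolation matrices
        (half-pixel-center convention); a fixed linear map, so the adjoint is
        the transposed matrices."""
        b, h, w, c = self.data.shape
        ah = _interp_matrix(h, out_h)
        aw = _interp_matrix(w, out_w)
        out_data = np.einsum("oh,bhwc->bowc", ah, self.data)
        out_data = np.einsum("pw,bowc->bopc", aw, out_data)
        out = self._make(out_data, (self,), None)
        if out.requires_grad:
            def backward(g):
                gi = np.einsum("pw,bopc->bowc", aw, g)
                gi = np.einsum("oh,bowc->bhwc", ah, gi)
                self._accum(gi)
            out._backward = backward
        return out


def _sliding_sum1d(a: np.ndarray, win: int, axis: int) -> np.ndarray:
    c = np.cumsum(a, axis=axis)
    pad = np.zeros_like(np.take(c, [0], axis=axis))
    c = np.concatenate([pad, c], axis=axis)
    n = a.shape[axis]
    hi = np.take(c, range(win, n + 1), axis=axis)
    lo = np.take(c, range(0, n - win + 1), axis=axis)
    return hi - lo


def _sliding_sum2d(a: np.ndarray, win: int) -> np.ndarray:
    return _sliding_sum1d(_sliding_sum1d(a, win, axis=-2), win, axis=-1)


_INTERP_CACHE: dict = {}


def _interp_matrix(n_in: int, n_out: int) -> np.ndarray:
    """Row-stochastic 1D bilinear interpolation matrix (n_out, n_in)."""
    key = (n_in, n_out)
    if key in _INTERP_CACHE:
        return _INTERP_CACHE[key]
    a = np.zeros((n_out, n_in))
    if n_in == 1:
        a[:, 0] = 1.0
    else:
        src = (np.arange(n_out) + 0.5) * n_in / n_out - 0.5
        src = np.clip(src, 0.0, n_in - 1.0)
        lo = np.floor(src).astype(int)
        hi = np.minimum(lo + 1, n_in - 1)
        frac = src - lo
        a[np.arange(n_out), lo] += 1.0 - frac
        a[np.arange(n_out), hi] += frac
    _INTERP_CACHE[key] = a
    return a
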