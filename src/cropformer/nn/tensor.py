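"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Supports exactly the operations the sequence encoder needs: broadcasted
arithmetic, (batched) matrix products, elementwise nonlinearities,
reductions, shape manipulation, slicing/padding and a numerically stable
softmax.  Gradients are accumulated by a topological backward sweep; every
op's backward is covered by finite-difference tests.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "softmax", "pad_time", "where", "set_default_dtype", "default_dtype"]

#: Engine-wide floating dtype. float32 is the training default; gradient
#: verification tests switch to float64 for finite-difference accuracy.
DTYPE = np.float32


def set_default_dtype(dtype) -> None:
    global DTYPE
    if np.dtype(dtype) not in (np.dtype(np.float32), np.dtype(np.float64)):
        raise ValueError("dtype must be float32 or float64")
    DTYPE = np.dtype(dtype).type


def default_dtype():
    return DTYPE


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after NumPy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, (g, s) in enumerate(zip(grad.shape, shape)):
        if s == 1 and g != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


def _as_tensor(x) -> "Tensor":
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=DTYPE))


class Tensor:
    """An n-d array node in a dynamically built computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- graph construction -------------------------------------------------

    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(p for p in parents if p.requires_grad)
            out._backward = backward
        return out

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- arithmetic ---------------------------------------------------------

    def __add__(self, other):
        other = _as_tensor(other)
        data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.shape))

        return Tensor._make(data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            self._accum(-g)

        return Tensor._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __mul__(self, other):
        other = _as_tensor(other)
        data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape))

        return Tensor._make(data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _as_tensor(other)
        data = self.data / other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accum(
                    _unbroadcast(-g * self.data / other.data**2, other.shape)
                )

        return Tensor._make(data, (self, other), backward)

    def __rtruediv__(self, other):
        return _as_tensor(other) / self

    def __pow__(self, p: float):
        data = self.data**p

        def backward(g):
            self._accum(g * p * self.data ** (p - 1))

        return Tensor._make(data, (self,), backward)

    def __matmul__(self, other):
        other = _as_tensor(other)
        data = np.matmul(self.data, other.data)

        def backward(g):
            if self.requires_grad:
                ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
                self._accum(_unbroadcast(ga, self.shape))
            if other.requires_grad:
                gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
                other._accum(_unbroadcast(gb, other.shape))

        return Tensor._make(data, (self, other), backward)

    # -- elementwise nonlinearities ------------------------------------------

    def exp(self):
        data = np.exp(self.data)

        def backward(g):
            self._accum(g * data)

        return Tensor._make(data, (self,), backward)

    def log(self):
        def backward(g):
            self._accum(g / self.data)

        return Tensor._make(np.log(self.data), (self,), backward)

    def sigmoid(self):
        data = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            self._accum(g * data * (1.0 - data))

        return Tensor._make(data, (self,), backward)

    def tanh(self):
        data = np.tanh(self.data)

        def backward(g):
            self._accum(g * (1.0 - data**2))

        return Tensor._make(data, (self,), backward)

    # -- reductions -----------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.shape).copy())

        return Tensor._make(data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # -- shape manipulation ----------------------------------------------------

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape

        def backward(g):
            self._accum(g.reshape(old))

        return Tensor._make(self.data.reshape(shape), (self,), backward)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def backward(g):
            self._accum(np.transpose(g, inv))

        return Tensor._make(np.transpose(self.data, axes), (self,), backward)

    def __getitem__(self, idx):
        def backward(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accum(full)

        return Tensor._make(self.data[idx], (self,), backward)

    # -- autodiff driver --------------------------------------------------------

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            # take ownership only when g is a view or wrong dtype
            if isinstance(g, np.ndarray) and g.base is None and g.dtype == DTYPE:
                self.grad = g
            else:
                self.grad = np.array(g, dtype=DTYPE)
        else:
            self.grad = self.grad + g

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this node (a scalar unless ``grad`` is given)."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() on non-scalar requires an explicit grad")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
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
        self._accum(np.asarray(grad, dtype=DTYPE))
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"


# -- free functions ---------------------------------------------------------------


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    """Concatenate tensors along ``axis``."""
    tensors = [_as_tensor(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._accum(piece)

    return Tensor._make(data, tuple(tensors), backward)


def where(cond: np.ndarray, a, b) -> Tensor:
    """Elementwise select; ``cond`` is a constant boolean array."""
    a, b = _as_tensor(a), _as_tensor(b)
    data = np.where(cond, a.data, b.data)

    def backward(g):
        if a.requires_grad:
            a._accum(_unbroadcast(np.where(cond, g, 0.0), a.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(np.where(cond, 0.0, g), b.shape))

    return Tensor._make(data, (a, b), backward)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Numerically stable softmax along ``axis`` (fused node)."""
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    s = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        dot = (g * s).sum(axis=axis, keepdims=True)
        x._accum(s * (g - dot))

    return Tensor._make(s, (x,), backward)


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Normalization over the last axis with affine parameters (fused node)."""
    mu = x.data.mean(axis=-1, keepdims=True)
    xc = x.data - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    out = xhat * gamma.data + beta.data

    def backward(g):
        if gamma.requires_grad:
            axes = tuple(range(g.ndim - 1))
            gamma._accum((g * xhat).sum(axis=axes))
        if beta.requires_grad:
            axes = tuple(range(g.ndim - 1))
            beta._accum(g.sum(axis=axes))
        if x.requires_grad:
            gy = g * gamma.data
            m1 = gy.mean(axis=-1, keepdims=True)
            m2 = (gy * xhat).mean(axis=-1, keepdims=True)
            x._accum((gy - m1 - xhat * m2) * inv)

    return Tensor._make(out, (x, gamma, beta), backward)


def depthwise_conv_time(x: Tensor, w: Tensor, b: Tensor, padding: int) -> Tensor:
    """Per-channel temporal convolution of an ``n x T x C`` tensor.

    ``w`` has shape ``(kernel, C)`` and ``b`` shape ``(C,)``.  Fused into a
    single graph node with a hand-derived backward (cross-correlation with
    the flipped kernel) to keep the op count low on the training path.
    """
    kernel = w.shape[0]
    T = x.shape[1]
    xp = np.pad(x.data, ((0, 0), (padding, padding), (0, 0)))
    out = np.zeros_like(x.data)
    for k in range(kernel):
        out += xp[:, k : k + T, :] * w.data[k]
    out += b.data

    def backward(g):
        if x.requires_grad:
            gp = np.pad(g, ((0, 0), (padding, padding), (0, 0)))
            gx = np.zeros_like(x.data)
            for k in range(kernel):
                # correlation of the upstream gradient with the flipped kernel
                gx += gp[:, k : k + T, :] * w.data[kernel - 1 - k]
            x._accum(gx)
        if w.requires_grad:
            gw = np.empty_like(w.data)
            for k in range(kernel):
                gw[k] = (xp[:, k : k + T, :] * g).sum(axis=(0, 1))
            w._accum(gw)
        if b.requires_grad:
            b._accum(g.sum(axis=(0, 1)))

    return Tensor._make(out, (x, w, b), backward)


def pad_time(x: Tensor, before: int, after: int) -> Tensor:
    """Zero-pad an ``n x T x C`` tensor along the time (middle) axis."""
    widths = ((0, 0), (before, after), (0, 0))
    data = np.pad(x.data, widths)
    T = x.shape[1]

    def backward(g):
        x._accum(g[:, before : before + T, :])

    return Tensor._make(data, (x,), backward)
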