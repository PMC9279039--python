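"""Minimal reverse-mode automatic differentiation over numpy arrays.

Just enough machinery for a small capsule network on a single CPU: elementwise
arithmetic with broadcasting, matmul, reductions, ReLU/exp/sqrt, softmax, a
strided im2col conv2d primitive, and an Adam optimizer. Gradients are
accumulated by reverse topological traversal from a scalar loss; correctness
is pinned by finite-difference checks in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "conv2d", "softmax", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """A numpy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- graph plumbing ----------------------------------------------------

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @staticmethod
    def _node(data, parents, backward) -> "Tensor":
        out = Tensor(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    @property
    def shape(self):
        return self.data.shape

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar")
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
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    def _accum(self, grad: np.ndarray) -> None:
        if not self.requires_grad:
            return
        grad = _unbroadcast(np.asarray(grad, dtype=np.float64), self.data.shape)
        self.grad = grad if self.grad is None else self.grad + grad

    # -- arithmetic --------------------------------------------------------

    def __add__(self, other):
        other = Tensor._lift(other)

        def backward(g):
            self._accum(g)
            other._accum(g)

        return Tensor._node(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            self._accum(-g)

        return Tensor._node(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-Tensor._lift(other))

    def __rsub__(self, other):
        return Tensor._lift(other) + (-self)

    def __mul__(self, other):
        other = Tensor._lift(other)

        def backward(g):
            self._accum(g * other.data)
            other._accum(g * self.data)

        return Tensor._node(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._lift(other)

        def backward(g):
            self._accum(g / other.data)
            other._accum(-g * self.data / (other.data**2))

        return Tensor._node(self.data / other.data, (self, other), backward)

    def __rtruediv__(self, other):
        return Tensor._lift(other) / self

    def __pow__(self, p: float):
        def backward(g):
            self._accum(g * p * self.data ** (p - 1))

        return Tensor._node(self.data**p, (self,), backward)

    def __matmul__(self, other):
        other = Tensor._lift(other)

        def backward(g):
            self._accum(g @ np.swapaxes(other.data, -1, -2))
            other._accum(np.swapaxes(self.data, -1, -2) @ g)

        return Tensor._node(self.data @ other.data, (self, other), backward)

    # -- shape ops ---------------------------------------------------------

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape

        def backward(g):
            self._accum(g.reshape(old))

        return Tensor._node(self.data.reshape(shape), (self,), backward)

    def transpose(self, *axes):
        if not axes:
            axes = tuple(reversed(range(self.data.ndim)))
        inv = np.argsort(axes)

        def backward(g):
            self._accum(g.transpose(inv))

        return Tensor._node(self.data.transpose(axes), (self,), backward)

    def expand_dims(self, axis: int):
        def backward(g):
            self._accum(np.squeeze(g, axis=axis))

        return Tensor._node(np.expand_dims(self.data, axis), (self,), backward)

    # -- reductions & elementwise -----------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        shape = self.data.shape

        def backward(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis=axis)
            self._accum(np.broadcast_to(g, shape))

        return Tensor._node(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def relu(self):
        mask = self.data > 0

        def backward(g):
            self._accum(g * mask)

        return Tensor._node(self.data * mask, (self,), backward)

    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            self._accum(g * out_data)

        return Tensor._node(out_data, (self,), backward)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def backward(g):
            self._accum(g * 0.5 / out_data)

        return Tensor._node(out_data, (self,), backward)


def softmax(x: Tensor, axis: int) -> Tensor:
    """Numerically stable softmax along ``axis`` (max subtracted as a constant)."""
    shift = x - Tensor(x.data.max(axis=axis, keepdims=True))
    e = shift.exp()
    return e / e.sum(axis=axis, keepdims=True)


def _im2col(x: np.ndarray, k: int, stride: int) -> np.ndarray:
    """(B, C, H, W) -> (B, Ho*Wo, C*k*k) patch matrix."""
    windows = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
    windows = windows[:, :, ::stride, ::stride]  # (B, C, Ho, Wo, k, k)
    B, C, Ho, Wo, _, _ = windows.shape
    return (
        windows.transpose(0, 2, 3, 1, 4, 5).reshape(B, Ho * Wo, C * k * k),
        Ho,
        Wo,
    )


def _col2im(cols: np.ndarray, x_shape, k: int, stride: int, Ho: int, Wo: int) -> np.ndarray:
    B, C, H, W = x_shape
    gx = np.zeros((B, C, H, W))
    patches = cols.reshape(B, Ho, Wo, C, k, k).transpose(0, 3, 1, 2, 4, 5)
    for di in range(k):
        for dj in range(k):
            gx[:, :, di : di + Ho * stride : stride, dj : dj + Wo * stride : stride] += patches[
                :, :, :, :, di, dj
            ]
    return gx


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, stride: int = 1) -> Tensor:
    """Valid-mode 2D convolution (cross-correlation): (B,Cin,H,W) * (Cout,Cin,k,k)."""
    B, Cin, H, W = x.data.shape
    Cout, Cin_w, k, _ = w.data.shape
    if Cin != Cin_w:
        raise ValueError(f"channel mismatch: input {Cin}, kernel {Cin_w}")
    if k > H or k > W:
        raise ValueError(f"kernel {k} larger than input {H}x{W}")
    cols, Ho, Wo = _im2col(x.data, k, stride)
    wmat = w.data.reshape(Cout, -1)
    out_data = (cols @ wmat.T).transpose(0, 2, 1).reshape(B, Cout, Ho, Wo)
    if b is not None:
        out_data = out_data + b.data.reshape(1, Cout, 1, 1)

    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        gmat = g.reshape(B, Cout, Ho * Wo).transpose(0, 2, 1)  # (B, Ho*Wo, Cout)
        if w.requires_grad:
            w._accum(np.einsum("bpo,bpi->oi", gmat, cols).reshape(w.data.shape))
        if x.requires_grad:
            x._accum(_col2im(gmat @ wmat, x.data.shape, k, stride, Ho, Wo))
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))

    return Tensor._node(out_data, parents, backward)


class Adam:
    """Adaptive-moment gradient descent over a list of parameter Tensors."""

    def __init__(self, params, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * g
            self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * g * g
            mhat = self.m[i] / (1 - self.beta1**self.t)
            vhat = self.v[i] / (1 - self.beta2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
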