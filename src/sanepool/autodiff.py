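"""Minimal reverse-mode automatic differentiation over dense numpy arrays.

The pooling model trains on per-sample molecular networks of at most a few
thousand nodes, so a small dynamic tape over dense ``numpy`` arrays is all
that is needed: every operation records a backward closure and ``backward()``
walks the tape in reverse topological order.  The op set is deliberately
restricted to what the model uses — elementwise arithmetic, matmul,
activations, reductions, row/submatrix gathers and a fused pairwise MLP.

Shapes are kept two-dimensional throughout (vectors are column matrices);
broadcasting follows numpy semantics and gradients are un-broadcast back to
the operand shape.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "astensor", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` over axes that numpy broadcasting expanded from ``shape``."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array plus gradient bookkeeping."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False, _prev: tuple = ()):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._prev = _prev

    # -- bookkeeping ------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def zero_grad(self) -> None:
        self.grad = None

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other):
        other = astensor(other)
        out = Tensor(self.data + other.data, _prev=(self, other))

        def bw(g):
            self._accum(_unbroadcast(g, self.data.shape))
            other._accum(_unbroadcast(g, other.data.shape))

        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, _prev=(self,))
        out._backward = lambda g: self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-astensor(other))

    def __rsub__(self, other):
        return astensor(other) + (-self)

    def __mul__(self, other):
        other = astensor(other)
        out = Tensor(self.data * other.data, _prev=(self, other))

        def bw(g):
            self._accum(_unbroadcast(g * other.data, self.data.shape))
            other._accum(_unbroadcast(g * self.data, other.data.shape))

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = astensor(other)
        out = Tensor(self.data / other.data, _prev=(self, other))

        def bw(g):
            self._accum(_unbroadcast(g / other.data, self.data.shape))
            other._accum(
                _unbroadcast(-g * self.data / (other.data ** 2), other.data.shape)
            )

        out._backward = bw
        return out

    def __pow__(self, exponent: float):
        if not np.isscalar(exponent):
            raise TypeError("only scalar exponents are supported")
        out = Tensor(self.data ** exponent, _prev=(self,))

        def bw(g):
            self._accum(g * exponent * self.data ** (exponent - 1))

        out._backward = bw
        return out

    def __matmul__(self, other):
        other = astensor(other)
        out = Tensor(self.data @ other.data, _prev=(self, other))

        def bw(g):
            self._accum(g @ other.data.T)
            other._accum(self.data.T @ g)

        out._backward = bw
        return out

    # -- elementwise nonlinearities --------------------------------------
    def tanh(self):
        y = np.tanh(self.data)
        out = Tensor(y, _prev=(self,))
        out._backward = lambda g: self._accum(g * (1.0 - y ** 2))
        return out

    def relu(self):
        mask = self.data > 0
        out = Tensor(np.where(mask, self.data, 0.0), _prev=(self,))
        out._backward = lambda g: self._accum(g * mask)
        return out

    def leaky_relu(self, alpha: float = 0.1):
        slope = np.where(self.data > 0, 1.0, alpha)
        out = Tensor(self.data * slope, _prev=(self,))
        out._backward = lambda g: self._accum(g * slope)
        return out

    def abs(self):
        s = np.sign(self.data)
        out = Tensor(np.abs(self.data), _prev=(self,))
        out._backward = lambda g: self._accum(g * s)
        return out

    def sqrt(self):
        y = np.sqrt(self.data)
        out = Tensor(y, _prev=(self,))
        # subgradient 0 at exactly 0 to avoid inf on padded rows
        out._backward = lambda g: self._accum(
            g * np.where(y > 0, 0.5 / np.where(y > 0, y, 1.0), 0.0)
        )
        return out

    def clip_min(self, lo: float):
        """max(x, lo); gradient passes only where x > lo."""
        mask = self.data > lo
        out = Tensor(np.where(mask, self.data, lo), _prev=(self,))
        out._backward = lambda g: self._accum(g * mask)
        return out

    # -- reductions & reshaping ------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _prev=(self,))

        def bw(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape).copy())

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def transpose(self):
        out = Tensor(self.data.T, _prev=(self,))
        out._backward = lambda g: self._accum(g.T)
        return out

    @property
    def T(self):
        return self.transpose()

    def take_rows(self, idx):
        """Gather rows ``idx`` (repeats allowed; gradients scatter-add back)."""
        idx = np.asarray(idx, dtype=np.intp)
        out = Tensor(self.data[idx], _prev=(self,))

        def bw(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accum(full)

        out._backward = bw
        return out

    def take_submatrix(self, idx):
        """Gather the square submatrix at rows/cols ``idx`` (np.ix_ semantics)."""
        idx = np.asarray(idx, dtype=np.intp)
        out = Tensor(self.data[np.ix_(idx, idx)], _prev=(self,))

        def bw(g):
            full = np.zeros_like(self.data)
            np.add.at(full, np.ix_(idx, idx), g)
            self._accum(full)

        out._backward = bw
        return out

    def symmetrize(self):
        """(X + Xᵀ)/2 — how trainable edge-weight matrices enter the graph."""
        return (self + self.transpose()) * 0.5

    # -- fused ops --------------------------------------------------------
    def pairwise_mlp(self, w_left: "Tensor", w_right: "Tensor", b1: "Tensor",
                     w2: "Tensor", b2: "Tensor"):
        """relu(MLP(Hi ∥ Hj)) for all node pairs, as an n×n matrix.

        The concatenated first layer is split into its left/right halves so
        the whole pairwise grid is a broadcast sum of two n×m maps; the
        backward pass is hand-written to avoid materialising gradients of a
        3-D intermediate more than once.
        """
        H = self
        L = H.data @ w_left.data          # n×m
        R = H.data @ w_right.data         # n×m
        pre = L[:, None, :] + R[None, :, :] + b1.data.reshape(1, 1, -1)
        hid = np.maximum(pre, 0.0)        # n×n×m
        raw = hid @ w2.data.reshape(-1) + b2.data.item()  # n×n
        out_data = np.maximum(raw, 0.0)
        out = Tensor(out_data, _prev=(H, w_left, w_right, b1, w2, b2))

        def bw(g):
            g_raw = g * (raw > 0)                          # n×n
            w2._accum((hid * g_raw[:, :, None]).sum(axis=(0, 1)).reshape(w2.data.shape))
            b2._accum(np.array(g_raw.sum()).reshape(b2.data.shape))
            g_hid = g_raw[:, :, None] * w2.data.reshape(1, 1, -1)
            g_pre = g_hid * (pre > 0)                      # n×n×m
            b1._accum(g_pre.sum(axis=(0, 1)).reshape(b1.data.shape))
            gL = g_pre.sum(axis=1)                         # n×m
            gR = g_pre.sum(axis=0)                         # n×m
            w_left._accum(H.data.T @ gL)
            w_right._accum(H.data.T @ gR)
            H._accum(gL @ w_left.data.T + gR @ w_right.data.T)

        out._backward = bw
        return out

    # -- engine -----------------------------------------------------------
    def backward(self, grad=None) -> None:
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
                stack.append((p, False))
        if grad is None:
            grad = np.ones_like(self.data)
        self._accum(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


def astensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


class Adam:
    """Adam optimiser over a list of parameter tensors."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        if self.lr == 0.0:
            return
        self.t += 1
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
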