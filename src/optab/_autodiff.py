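"""Minimal reverse-mode automatic differentiation over numpy arrays.

The differential-equation model in :mod:`optab.tecde` is built from small
multilayer perceptrons composed through fixed-step Runge--Kutta integration,
so the full forward pass is an ordinary numpy computation graph.  This module
records that graph on a tape and back-propagates through it.  It supports
exactly the operations the model needs (affine maps, tanh/sigmoid, batched
matrix--vector contraction, elementwise arithmetic with broadcasting,
reductions, slicing and concatenation) and nothing more.

Gradients are checked against central finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "stack_params", "MLP", "Adam", "fused_mlp", "fused_mlp_bmv"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` over axes that were broadcast to reach `grad.shape`."""
    if grad.shape == shape:
        return grad
    # sum leading extra axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A node in the computation graph wrapping a float64 ndarray."""

    __slots__ = ("data", "grad", "_parents", "_backward", "requires_grad")

    def __init__(self, data, parents=(), backward=None, requires_grad=False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self._parents = parents
        self._backward = backward
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.data.shape

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self) -> None:
        """Back-propagate from this (scalar or any-shape) tensor."""
        topo, seen = [], set()

        def visit(node):
            stack = [(node, False)]
            while stack:
                n, done = stack.pop()
                if done:
                    topo.append(n)
                    continue
                if id(n) in seen or not n.requires_grad:
                    continue
                seen.add(id(n))
                stack.append((n, True))
                for p in n._parents:
                    stack.append((p, False))

        visit(self)
        self._accumulate(np.ones_like(self.data))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # ------------------------------------------------------------- arithmetic
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.data + other.data, (self, other))

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.data.shape))

        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, (self,))
        out._backward = lambda g: self.requires_grad and self._accumulate(-g)
        return out

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data * other.data, (self, other))

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        out = Tensor(self.data / other.data, (self, other))

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(
                    _unbroadcast(-g * self.data / other.data**2, other.data.shape)
                )

        out._backward = bw
        return out

    def __matmul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data @ other.data, (self, other))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g @ other.data.T)
            if other.requires_grad:
                other._accumulate(self.data.T @ g)

        out._backward = bw
        return out

    def bmv(self, vec: "Tensor") -> "Tensor":
        """Batched matrix--vector product: (B,P,C) x (B,C) -> (B,P)."""
        vec = self._lift(vec)
        out = Tensor(np.einsum("bpc,bc->bp", self.data, vec.data), (self, vec))

        def bw(g):
            if self.requires_grad:
                self._accumulate(np.einsum("bp,bc->bpc", g, vec.data))
            if vec.requires_grad:
                vec._accumulate(np.einsum("bp,bpc->bc", g, self.data))

        out._backward = bw
        return out

    # ------------------------------------------------------------ elementwise
    def tanh(self):
        y = np.tanh(self.data)
        out = Tensor(y, (self,))
        out._backward = lambda g: self.requires_grad and self._accumulate(
            g * (1.0 - y**2)
        )
        return out

    def sigmoid(self):
        y = 1.0 / (1.0 + np.exp(-np.clip(self.data, -500, 500)))
        out = Tensor(y, (self,))
        out._backward = lambda g: self.requires_grad and self._accumulate(
            g * y * (1.0 - y)
        )
        return out

    def exp(self):
        y = np.exp(self.data)
        out = Tensor(y, (self,))
        out._backward = lambda g: self.requires_grad and self._accumulate(g * y)
        return out

    def log(self):
        out = Tensor(np.log(self.data), (self,))
        out._backward = lambda g: self.requires_grad and self._accumulate(
            g / self.data
        )
        return out

    def clip(self, lo, hi):
        """Clamp values; gradient passes through unclipped entries only."""
        y = np.clip(self.data, lo, hi)
        inside = (self.data > lo) & (self.data < hi)
        out = Tensor(y, (self,))
        out._backward = lambda g: self.requires_grad and self._accumulate(g * inside)
        return out

    def grad_reverse(self):
        """Identity forward, negated gradient backward (adversarial balancing)."""
        out = Tensor(self.data.copy(), (self,))
        out._backward = lambda g: self.requires_grad and self._accumulate(-g)
        return out

    def square(self):
        out = Tensor(self.data**2, (self,))
        out._backward = lambda g: self.requires_grad and self._accumulate(
            g * 2.0 * self.data
        )
        return out

    # -------------------------------------------------------------- reductions
    def sum(self, axis=None):
        out = Tensor(self.data.sum(axis=axis), (self,))

        def bw(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.data.shape).copy())
            else:
                self._accumulate(
                    np.broadcast_to(np.expand_dims(g, axis), self.data.shape).copy()
                )

        out._backward = bw
        return out

    def mean(self, axis=None):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis) * (1.0 / n)

    # ------------------------------------------------------------ shape munge
    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), (self,))
        out._backward = lambda g: self.requires_grad and self._accumulate(
            g.reshape(self.data.shape)
        )
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], (self,))

        def bw(g):
            if not self.requires_grad:
                return
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accumulate(full)

        out._backward = bw
        return out


def concat(tensors, axis=-1) -> Tensor:
    """Concatenate tensors along `axis`, differentiable."""
    tensors = [Tensor._lift(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    out._backward = bw
    return out


def fused_mlp(x: Tensor, weights, biases) -> Tensor:
    """Perceptron forward (tanh hidden layers, linear output) as one tape node.

    Equivalent to chaining matmul/add/tanh Tensors but stores only the
    post-activation arrays needed for the backward pass, so large
    intermediate buffers are freed immediately and recycled.
    """
    x = Tensor._lift(x)
    a = x.data
    acts = [a]
    last = len(weights) - 1
    for i, (W, b) in enumerate(zip(weights, biases)):
        z = a @ W.data + b.data
        a = z if i == last else np.tanh(z)
        acts.append(a)
    out = Tensor(a, (x, *weights, *biases))

    def bw(g):
        grad = g
        for i in reversed(range(len(weights))):
            W, b = weights[i], biases[i]
            if i != last:
                grad = grad * (1.0 - acts[i + 1] ** 2)
            if b.requires_grad:
                b._accumulate(grad.sum(axis=0))
            if W.requires_grad:
                W._accumulate(acts[i].T @ grad)
            if i > 0 or x.requires_grad:
                grad = grad @ W.data.T
        if x.requires_grad:
            x._accumulate(grad)

    out._backward = bw
    return out


def fused_mlp_bmv(x: Tensor, weights, biases, dX: np.ndarray, P: int, C: int) -> Tensor:
    """Contract an MLP's (B, P*C) output with a constant control slope (B, C).

    Computes einsum('bpc,bc->bp', mlp(x).reshape(B,P,C), dX) without keeping
    the large flat output alive; the backward pass reconstructs the output
    gradient from the slope.  `dX` carries no gradient (control paths are
    data, not parameters).
    """
    x = Tensor._lift(x)
    a = x.data
    acts = [a]
    last = len(weights) - 1
    for i, (W, b) in enumerate(zip(weights, biases)):
        z = a @ W.data + b.data
        a = z if i == last else np.tanh(z)
        acts.append(a)
    B = a.shape[0]
    y = np.einsum("bpc,bc->bp", a.reshape(B, P, C), dX)
    acts[-1] = None  # the flat field output is not needed for backward
    out = Tensor(y, (x, *weights, *biases))

    def bw(g):
        grad = np.einsum("bp,bc->bpc", g, dX).reshape(B, P * C)
        for i in reversed(range(len(weights))):
            W, b = weights[i], biases[i]
            if i != last:
                grad = grad * (1.0 - acts[i + 1] ** 2)
            if b.requires_grad:
                b._accumulate(grad.sum(axis=0))
            if W.requires_grad:
                W._accumulate(acts[i].T @ grad)
            if i > 0 or x.requires_grad:
                grad = grad @ W.data.T
        if x.requires_grad:
            x._accumulate(grad)

    out._backward = bw
    return out


# ---------------------------------------------------------------------- layers
class MLP:
    """Two-hidden-layer perceptron with tanh activations (sizes configurable).

    Weight initialization follows the Glorot uniform scheme with a
    caller-supplied generator so that model construction is reproducible.
    """

    def __init__(self, n_in, n_out, hidden=(32, 32), rng=None, final_scale=1.0):
        rng = rng or np.random.default_rng(0)
        dims = [n_in, *hidden, n_out]
        self.weights, self.biases = [], []
        for i, (a, b) in enumerate(zip(dims[:-1], dims[1:])):
            lim = np.sqrt(6.0 / (a + b))
            w = rng.uniform(-lim, lim, size=(a, b))
            if i == len(dims) - 2:
                w *= final_scale
            self.weights.append(Tensor(w, requires_grad=True))
            self.biases.append(Tensor(np.zeros(b), requires_grad=True))

    def __call__(self, x: Tensor) -> Tensor:
        return fused_mlp(x, self.weights, self.biases)

    @property
    def params(self):
        return [*self.weights, *self.biases]


def stack_params(*modules):
    out = []
    for m in modules:
        out.extend(m.params if hasattr(m, "params") else [m])
    return out


class Adam:
    """Adam optimizer over a flat list of parameter Tensors."""

    def __init__(self, params, lr=1e-2, betas=(0.9, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g**2
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def state_dict(self):
        return {"m": self.m, "v": self.v, "t": self.t}
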