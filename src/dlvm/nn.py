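"""Minimal reverse-mode automatic differentiation and neural-net layers.

The package's generative model and classifiers are small multilayer
perceptrons trained by stochastic gradient ascent.  This module provides the
machinery for that: a :class:`Tensor` wrapping a numpy array with a vector-
Jacobian-product graph, a handful of differentiable primitives (enough for
variational-autoencoder objectives: Gaussian and Bernoulli log-likelihoods,
closed-form KL terms, softmax heads), :class:`Linear`/:class:`MLP` layers and
an :class:`Adam` optimizer.

Everything is float64 numpy; gradients are exact (checked against finite
differences in the test suite).  No GPU, no broadcasting surprises beyond
standard numpy rules: gradients of broadcast operands are summed back to the
operand's shape.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np
from scipy.special import expit

__all__ = [
    "Tensor",
    "concat",
    "sigmoid",
    "tanh",
    "relu",
    "prelu",
    "softplus",
    "exp",
    "log",
    "logsumexp",
    "Linear",
    "MLP",
    "Adam",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    """A numpy array plus the local backward rules that produced it."""

    __slots__ = ("data", "grad", "requires_grad", "_parents")

    def __init__(self, data, requires_grad: bool = False, parents=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self._parents: list[tuple["Tensor", Callable[[np.ndarray], np.ndarray]]] = (
            parents or []
        )
        self.requires_grad = requires_grad or bool(self._parents)

    # -- graph -----------------------------------------------------------
    def backward(self) -> None:
        """Accumulate gradients of ``self`` (summed to a scalar) into leaves."""
        topo: list[Tensor] = []
        seen: set[int] = set()

        stack = [(self, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for parent, _ in node._parents:
                if id(parent) not in seen:
                    stack.append((parent, False))

        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node.grad is None or not node._parents:
                continue
            g = node.grad
            for parent, vjp in node._parents:
                if not parent.requires_grad:
                    continue
                pg = _unbroadcast(vjp(g), parent.data.shape)
                parent.grad = pg if parent.grad is None else parent.grad + pg

    # -- arithmetic ------------------------------------------------------
    def __add__(self, other):
        o = _as_tensor(other)
        return Tensor(
            self.data + o.data,
            parents=[(self, lambda g: g), (o, lambda g: g)],
        )

    __radd__ = __add__

    def __neg__(self):
        return Tensor(-self.data, parents=[(self, lambda g: -g)])

    def __sub__(self, other):
        o = _as_tensor(other)
        return Tensor(
            self.data - o.data,
            parents=[(self, lambda g: g), (o, lambda g: -g)],
        )

    def __rsub__(self, other):
        return _as_tensor(other) - self

    def __mul__(self, other):
        o = _as_tensor(other)
        return Tensor(
            self.data * o.data,
            parents=[(self, lambda g: g * o.data), (o, lambda g: g * self.data)],
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        o = _as_tensor(other)
        return Tensor(
            self.data / o.data,
            parents=[
                (self, lambda g: g / o.data),
                (o, lambda g: -g * self.data / (o.data**2)),
            ],
        )

    def __rtruediv__(self, other):
        return _as_tensor(other) / self

    def __pow__(self, p):
        if not isinstance(p, (int, float)):
            raise TypeError("only constant exponents are supported")
        return Tensor(
            self.data**p,
            parents=[(self, lambda g: g * p * self.data ** (p - 1))],
        )

    def __matmul__(self, other):
        o = _as_tensor(other)
        return Tensor(
            self.data @ o.data,
            parents=[
                (self, lambda g: g @ o.data.T),
                (o, lambda g: self.data.T @ g),
            ],
        )

    # -- reductions ------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        shape = self.data.shape

        def vjp(g):
            if axis is None:
                return np.broadcast_to(g, shape).copy()
            gg = g if keepdims else np.expand_dims(g, axis)
            return np.broadcast_to(gg, shape).copy()

        return Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=[(self, vjp)])

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    @property
    def shape(self):
        return self.data.shape

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# -- elementwise primitives ----------------------------------------------

def exp(x: Tensor) -> Tensor:
    y = np.exp(x.data)
    return Tensor(y, parents=[(x, lambda g: g * y)])


def log(x: Tensor) -> Tensor:
    return Tensor(np.log(x.data), parents=[(x, lambda g: g / x.data)])


def tanh(x: Tensor) -> Tensor:
    y = np.tanh(x.data)
    return Tensor(y, parents=[(x, lambda g: g * (1.0 - y**2))])


def sigmoid(x: Tensor) -> Tensor:
    y = expit(x.data)
    return Tensor(y, parents=[(x, lambda g: g * y * (1.0 - y))])


def softplus(x: Tensor) -> Tensor:
    """log(1 + e^x), computed stably; derivative is the logistic function."""
    y = np.logaddexp(0.0, x.data)
    return Tensor(y, parents=[(x, lambda g: g * expit(x.data))])


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    return Tensor(x.data * mask, parents=[(x, lambda g: g * mask)])


def prelu(x: Tensor, slope: Tensor) -> Tensor:
    """Parametric ReLU: x for x>0, slope*x otherwise; slope is learnable."""
    return relu(x) - slope * relu(-x)


def logsumexp(x: Tensor, axis: int = 1, keepdims: bool = True) -> Tensor:
    m = x.data.max(axis=axis, keepdims=True)
    y = m + np.log(np.exp(x.data - m).sum(axis=axis, keepdims=True))
    if not keepdims:
        y = np.squeeze(y, axis=axis)

    def vjp(g):
        gg = g if keepdims else np.expand_dims(g, axis)
        yk = y if keepdims else np.expand_dims(y, axis)
        return gg * np.exp(x.data - yk)

    return Tensor(y, parents=[(x, vjp)])


def slice_cols(x: Tensor, lo: int, hi: int) -> Tensor:
    """Columns [lo, hi) of a 2-D tensor (used to split distribution heads)."""

    def vjp(g):
        out = np.zeros_like(x.data)
        out[:, lo:hi] = g
        return out

    return Tensor(x.data[:, lo:hi], parents=[(x, vjp)])


def concat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)
    out = np.concatenate([t.data for t in tensors], axis=axis)

    parents = []
    for i, t in enumerate(tensors):
        lo, hi = offsets[i], offsets[i + 1]

        def vjp(g, lo=lo, hi=hi):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            return g[tuple(sl)]

        parents.append((t, vjp))
    return Tensor(out, parents=parents)


# -- layers ---------------------------------------------------------------

_ACTIVATIONS: dict[str, Callable[..., Tensor]] = {
    "sigmoid": sigmoid,
    "tanh": tanh,
    "relu": relu,
    "softplus": softplus,
}


class Linear:
    """Affine layer with Glorot-uniform weight initialization."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        limit = np.sqrt(6.0 / (d_in + d_out))
        self.W = Tensor(rng.uniform(-limit, limit, size=(d_in, d_out)), requires_grad=True)
        self.b = Tensor(np.zeros(d_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b

    def parameters(self) -> list[Tensor]:
        return [self.W, self.b]


class MLP:
    """Fully connected network; hidden activation by name, linear output.

    ``activation="prelu"`` attaches one learnable slope per hidden layer
    (initialized at 0.25, the usual convention).
    """

    def __init__(
        self,
        d_in: int,
        hidden: Sequence[int],
        d_out: int,
        rng: np.random.Generator,
        activation: str = "sigmoid",
    ):
        if activation != "prelu" and activation not in _ACTIVATIONS:
            raise ValueError(
                f"unknown activation {activation!r}; choose from "
                f"{sorted(_ACTIVATIONS) + ['prelu']}"
            )
        self.activation = activation
        dims = [d_in, *hidden, d_out]
        self.layers = [Linear(a, b, rng) for a, b in zip(dims[:-1], dims[1:])]
        self.slopes = (
            [Tensor(np.array(0.25), requires_grad=True) for _ in hidden]
            if activation == "prelu"
            else []
        )

    def __call__(self, x: Tensor) -> Tensor:
        h = x
        for i, layer in enumerate(self.layers):
            h = layer(h)
            if i < len(self.layers) - 1:
                if self.activation == "prelu":
                    h = prelu(h, self.slopes[i])
                else:
                    h = _ACTIVATIONS[self.activation](h)
        return h

    def parameters(self) -> list[Tensor]:
        params = [p for layer in self.layers for p in layer.parameters()]
        params.extend(self.slopes)
        return params


class Adam:
    """Adam with optional L2 weight decay added to the raw gradient."""

    def __init__(
        self,
        params: Iterable[Tensor],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 0.0,
    ):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g**2
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


# -- likelihood / divergence helpers --------------------------------------

LOG2 = float(np.log(2.0))
LOG_2PI = float(np.log(2.0 * np.pi))


def bernoulli_loglik(x: np.ndarray, logits: Tensor) -> Tensor:
    """Row sums of log Bernoulli(x | sigmoid(logits)); x in {0,1}."""
    xt = Tensor(x)
    return (xt * logits - softplus(logits)).sum(axis=1)


def gaussian_loglik(x: np.ndarray, mu: Tensor, logvar: Tensor) -> Tensor:
    """Row sums of log N(x | mu, exp(logvar)) with diagonal covariance."""
    xt = Tensor(x)
    return (
        -0.5 * (LOG_2PI + logvar + (xt - mu) ** 2 / exp(logvar))
    ).sum(axis=1)


def kl_bernoulli_uniform(logits: Tensor) -> Tensor:
    """Row sums of KL(Bernoulli(sigmoid(l)) || Bernoulli(0.5)).

    Per dimension: log 2 + q*l - softplus(l), with q = sigmoid(l); always >= 0.
    """
    q = sigmoid(logits)
    return (LOG2 + q * logits - softplus(logits)).sum(axis=1)


def kl_gaussian_standard(mu: Tensor, logvar: Tensor) -> Tensor:
    """Row sums of KL(N(mu, exp(logvar)) || N(0, I))."""
    return (0.5 * (mu**2 + exp(logvar) - 1.0 - logvar)).sum(axis=1)


def kl_gaussian_gaussian(
    mu_q: Tensor, logvar_q: Tensor, mu_p: Tensor, logvar_p: Tensor
) -> Tensor:
    """Row sums of KL(N(mu_q, var_q) || N(mu_p, var_p)), both diagonal."""
    term = (
        exp(logvar_q - logvar_p)
        + (mu_q - mu_p) ** 2 / exp(logvar_p)
        - 1.0
        + logvar_p
        - logvar_q
    )
    return (0.5 * term).sum(axis=1)


def bounded_logvar(raw: Tensor, bound: float = 4.0) -> Tensor:
    """Squash a raw log-variance head into (-bound, bound) for stability."""
    return bound * tanh(raw / bound)
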