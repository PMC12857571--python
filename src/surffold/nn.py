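"""Minimal reverse-mode automatic differentiation and neural-network layers.

The learnable parts of the pipeline (chemical-feature MLPs, quasi-geodesic
convolutions, EdgeGraphConv, cross-attention, the one-shot decoder) are small
dense networks over per-protein tensors.  They are implemented here on a
compact tape-based autodiff engine over ``numpy.float64`` arrays: every
:class:`Tensor` records its parents and a backward closure, and
:meth:`Tensor.backward` walks the tape in reverse topological order.

Gradients of every primitive are verified against central finite differences
in the test suite; correctness, determinism and CPU-friendliness are the
design goals, not large-scale throughput.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np
from scipy.special import erf

__all__ = [
    "Tensor",
    "Parameter",
    "Module",
    "ModuleList",
    "Linear",
    "MLP",
    "LayerNorm",
    "MultiHeadAttention",
    "Adam",
    "concat",
    "take_rows",
    "index_add_rows",
    "softmax",
    "dropout",
    "gelu",
    "relu",
    "layer_norm",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over broadcast dimensions so it matches ``shape``."""
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with an optional gradient tape."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        _parents: tuple["Tensor", ...] = (),
        _backward: Callable[[np.ndarray], None] | None = None,
    ):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = requires_grad or any(p.requires_grad for p in _parents)
        self.grad: np.ndarray | None = None
        self._parents = _parents if self.requires_grad else ()
        self._backward = _backward if self.requires_grad else None

    # ------------------------------------------------------------------ infra
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this tensor (defaults to d(out)/d(out) = 1)."""
        if not self.requires_grad:
            raise RuntimeError("backward() on a tensor that does not require grad")
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
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        if grad is None:
            grad = np.ones_like(self.data)
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # ------------------------------------------------------------- arithmetic
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other) -> "Tensor":
        other = Tensor._lift(other)

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))

        return Tensor(self.data + other.data, _parents=(self, other), _backward=bwd)

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        def bwd(g):
            self._accumulate(-g)

        return Tensor(-self.data, _parents=(self,), _backward=bwd)

    def __sub__(self, other) -> "Tensor":
        return self + (-Tensor._lift(other))

    def __rsub__(self, other) -> "Tensor":
        return Tensor._lift(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = Tensor._lift(other)

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape))

        return Tensor(self.data * other.data, _parents=(self, other), _backward=bwd)

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        other = Tensor._lift(other)
        return self * other ** -1.0

    def __rtruediv__(self, other) -> "Tensor":
        return Tensor._lift(other) * self ** -1.0

    def __pow__(self, exponent: float) -> "Tensor":
        e = float(exponent)
        out_data = self.data ** e

        def bwd(g):
            self._accumulate(g * e * self.data ** (e - 1.0))

        return Tensor(out_data, _parents=(self,), _backward=bwd)

    def __matmul__(self, other) -> "Tensor":
        other = Tensor._lift(other)

        def bwd(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accumulate(_unbroadcast(ga, self.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accumulate(_unbroadcast(gb, other.shape))

        return Tensor(self.data @ other.data, _parents=(self, other), _backward=bwd)

    # ------------------------------------------------------------ elementwise
    def exp(self) -> "Tensor":
        out_data = np.exp(self.data)

        def bwd(g):
            self._accumulate(g * out_data)

        return Tensor(out_data, _parents=(self,), _backward=bwd)

    def log(self) -> "Tensor":
        def bwd(g):
            self._accumulate(g / self.data)

        return Tensor(np.log(self.data), _parents=(self,), _backward=bwd)

    def tanh(self) -> "Tensor":
        out_data = np.tanh(self.data)

        def bwd(g):
            self._accumulate(g * (1.0 - out_data**2))

        return Tensor(out_data, _parents=(self,), _backward=bwd)

    # ------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bwd(g):
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.shape).copy())
                return
            ax = axis if isinstance(axis, tuple) else (axis,)
            if not keepdims:
                g = np.expand_dims(g, ax)
            self._accumulate(np.broadcast_to(g, self.shape).copy())

        return Tensor(out_data, _parents=(self,), _backward=bwd)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # ----------------------------------------------------------------- shapes
    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.shape

        def bwd(g):
            self._accumulate(g.reshape(orig))

        return Tensor(self.data.reshape(shape), _parents=(self,), _backward=bwd)

    def transpose(self, *axes) -> "Tensor":
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = tuple(np.argsort(axes))

        def bwd(g):
            self._accumulate(g.transpose(inv))

        return Tensor(self.data.transpose(axes), _parents=(self,), _backward=bwd)


class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


# ------------------------------------------------------------------ functions
def relu(x: Tensor) -> Tensor:
    mask = (x.data > 0).astype(np.float64)

    def bwd(g):
        x._accumulate(g * mask)

    return Tensor(x.data * mask, _parents=(x,), _backward=bwd)


_INV_SQRT2 = 1.0 / np.sqrt(2.0)
_INV_SQRT2PI = 1.0 / np.sqrt(2.0 * np.pi)


def gelu(x: Tensor) -> Tensor:
    """Exact Gaussian-error-linear unit, 0.5 x (1 + erf(x/sqrt(2)))."""
    cdf = 0.5 * (1.0 + erf(x.data * _INV_SQRT2))
    pdf = _INV_SQRT2PI * np.exp(-0.5 * x.data**2)

    def bwd(g):
        x._accumulate(g * (cdf + x.data * pdf))

    return Tensor(x.data * cdf, _parents=(x,), _backward=bwd)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    s = e / e.sum(axis=axis, keepdims=True)

    def bwd(g):
        inner = (g * s).sum(axis=axis, keepdims=True)
        x._accumulate(s * (g - inner))

    return Tensor(s, _parents=(x,), _backward=bwd)


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x.data - x.data.max(axis=axis, keepdims=True)
    lse = np.log(np.exp(shifted).sum(axis=axis, keepdims=True))
    out_data = shifted - lse
    s = np.exp(out_data)

    def bwd(g):
        x._accumulate(g - s * g.sum(axis=axis, keepdims=True))

    return Tensor(out_data, _parents=(x,), _backward=bwd)


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            if t.requires_grad:
                t._accumulate(g[tuple(sl)])

    return Tensor(
        np.concatenate([t.data for t in tensors], axis=axis),
        _parents=tuple(tensors),
        _backward=bwd,
    )


def take_rows(x: Tensor, index: np.ndarray) -> Tensor:
    """Gather rows along axis 0; ``index`` may be any integer array."""
    index = np.asarray(index, dtype=np.intp)

    def bwd(g):
        gx = np.zeros_like(x.data)
        np.add.at(gx, index, g)
        x._accumulate(gx)

    return Tensor(x.data[index], _parents=(x,), _backward=bwd)


def index_add_rows(src: Tensor, index: np.ndarray, n_rows: int) -> Tensor:
    """Scatter-add rows of ``src`` into an ``(n_rows, ...)`` output (segment sum)."""
    index = np.asarray(index, dtype=np.intp)
    out_data = np.zeros((n_rows,) + src.shape[1:])
    np.add.at(out_data, index, src.data)

    def bwd(g):
        src._accumulate(g[index])

    return Tensor(out_data, _parents=(src,), _backward=bwd)


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    mu = x.mean(axis=-1, keepdims=True)
    xc = x - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    y = xc * (var + eps) ** -0.5
    return y * gamma + beta


def dropout(x: Tensor, p: float, rng: np.random.Generator, training: bool) -> Tensor:
    if not training or p <= 0.0:
        return x
    mask = (rng.random(x.shape) >= p).astype(np.float64) / (1.0 - p)
    return x * Tensor(mask)


# -------------------------------------------------------------------- modules
class Module:
    """Base class; collects :class:`Parameter` attributes recursively."""

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        seen: set[int] = set()
        for value in vars(self).values():
            if isinstance(value, Parameter) and id(value) not in seen:
                seen.add(id(value))
                params.append(value)
            elif isinstance(value, Module):
                for p in value.parameters():
                    if id(p) not in seen:
                        seen.add(id(p))
                        params.append(p)
        return params

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state_dict(self, arrays: Iterable[np.ndarray]) -> None:
        arrays = list(arrays)
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError(
                f"state has {len(arrays)} arrays, model has {len(params)} parameters"
            )
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError(f"shape mismatch {p.data.shape} vs {a.shape}")
            p.data = np.asarray(a, dtype=np.float64).copy()


class ModuleList(Module):
    def __init__(self, modules: Sequence[Module]):
        self._modules = list(modules)

    def __iter__(self):
        return iter(self._modules)

    def __len__(self) -> int:
        return len(self._modules)

    def __getitem__(self, i: int) -> Module:
        return self._modules[i]

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        for m in self._modules:
            params.extend(m.parameters())
        return params


class Linear(Module):
    """Affine map with Glorot-uniform weight initialization."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator, bias: bool = True):
        limit = np.sqrt(6.0 / (d_in + d_out))
        self.weight = Parameter(rng.uniform(-limit, limit, size=(d_in, d_out)))
        self.bias = Parameter(np.zeros(d_out)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class MLP(Module):
    """Stack of Linear layers with an activation between (not after) them."""

    def __init__(
        self,
        dims: Sequence[int],
        rng: np.random.Generator,
        activation: Callable[[Tensor], Tensor] = gelu,
    ):
        self.layers = ModuleList([Linear(a, b, rng) for a, b in zip(dims[:-1], dims[1:])])
        self.activation = activation

    def __call__(self, x: Tensor) -> Tensor:
        n = len(self.layers)
        for i, layer in enumerate(self.layers):
            x = layer(x)
            if i < n - 1:
                x = self.activation(x)
        return x


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        return layer_norm(x, self.gamma, self.beta, self.eps)


class MultiHeadAttention(Module):
    """Standard multi-head scaled-dot-product attention over L positions.

    Inputs are ``(L, d_model)``; queries, keys and values may come from
    different streams (cross-attention).
    """

    def __init__(self, d_model: int, n_heads: int, rng: np.random.Generator):
        if d_model % n_heads != 0:
            raise ValueError(f"n_heads={n_heads} does not divide d_model={d_model}")
        self.n_heads = n_heads
        self.d_head = d_model // n_heads
        self.wq = Linear(d_model, d_model, rng)
        self.wk = Linear(d_model, d_model, rng)
        self.wv = Linear(d_model, d_model, rng)
        self.wo = Linear(d_model, d_model, rng)

    def attention_weights(self, q_in: Tensor, k_in: Tensor) -> np.ndarray:
        """Attention probabilities (n_heads, L_q, L_k); diagnostic, no grad."""
        return self._attn(q_in, k_in)[1]

    def _attn(self, q_in: Tensor, k_in: Tensor):
        Lq, Lk = q_in.shape[0], k_in.shape[0]
        q = self.wq(q_in).reshape(Lq, self.n_heads, self.d_head).transpose(1, 0, 2)
        k = self.wk(k_in).reshape(Lk, self.n_heads, self.d_head).transpose(1, 0, 2)
        scores = (q @ k.transpose(0, 2, 1)) * (1.0 / np.sqrt(self.d_head))
        probs = softmax(scores, axis=-1)
        return q, probs.data, probs

    def __call__(self, q_in: Tensor, k_in: Tensor, v_in: Tensor) -> Tensor:
        Lq, Lk = q_in.shape[0], k_in.shape[0]
        _, _, probs = self._attn(q_in, k_in)
        v = self.wv(v_in).reshape(Lk, self.n_heads, self.d_head).transpose(1, 0, 2)
        out = (probs @ v).transpose(1, 0, 2).reshape(Lq, self.n_heads * self.d_head)
        return self.wo(out)


class Adam:
    """Adam optimizer (Kingma & Ba) with optional gradient clipping."""

    def __init__(
        self,
        params: Sequence[Parameter],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        grad_clip: float | None = None,
    ):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.grad_clip = grad_clip
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        grads = [p.grad if p.grad is not None else np.zeros_like(p.data) for p in self.params]
        if self.grad_clip is not None:
            norm = np.sqrt(sum(float((g**2).sum()) for g in grads))
            if norm > self.grad_clip:
                scale = self.grad_clip / (norm + 1e-12)
                grads = [g * scale for g in grads]
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g**2
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def state_dict(self) -> dict:
        return {"t": self.t, "m": [m.copy() for m in self.m], "v": [v.copy() for v in self.v]}

    def load_state_dict(self, state: dict) -> None:
        self.t = int(state["t"])
        self.m = [np.asarray(m, dtype=np.float64).copy() for m in state["m"]]
        self.v = [np.asarray(v, dtype=np.float64).copy() for v in state["v"]]
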