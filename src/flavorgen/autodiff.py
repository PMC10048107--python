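"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Implements exactly the tensor operations the gated graph network and its
training loop require: broadcast arithmetic, matmul, concatenation, row
padding, reductions, SELU/sigmoid/tanh, and a numerically stable
log-softmax.  Gradients flow through a topologically sorted tape; anything
wrapped in a plain ndarray (masks, one-hot targets) is treated as a
constant.  Also provides Linear/MLP/GRU building blocks with uniform
fan-in initialization and an Adam optimizer with multiplicative
learning-rate decay.
"""

from __future__ import annotations

import math
from typing import Callable, Iterable, Sequence

import numpy as np

Array = np.ndarray

_SELU_ALPHA = 1.6732632423543772
_SELU_SCALE = 1.0507009873554805


def _unbroadcast(grad: Array, shape: tuple[int, ...]) -> Array:
    """Reduce a broadcast gradient back to the original operand shape."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False,
                 parents: tuple = (), backward: Callable | None = None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: Array | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents
        self._backward = backward

    # -- basics ------------------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    # -- arithmetic ---------------------------------------------------------

    def __add__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def backward(grad):
            return (_unbroadcast(grad, self.shape),
                    _unbroadcast(grad, other.shape))

        out._backward = backward
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))
        out._backward = lambda grad: (-grad,)
        return out

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def backward(grad):
            return (_unbroadcast(grad * other.data, self.shape),
                    _unbroadcast(grad * self.data, other.shape))

        out._backward = backward
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data / other.data, parents=(self, other))

        def backward(grad):
            return (_unbroadcast(grad / other.data, self.shape),
                    _unbroadcast(-grad * self.data / other.data ** 2, other.shape))

        out._backward = backward
        return out

    def __pow__(self, exponent: float):
        out = Tensor(self.data ** exponent, parents=(self,))
        out._backward = lambda grad: (grad * exponent * self.data ** (exponent - 1),)
        return out

    def __matmul__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data @ other.data, parents=(self, other))

        def backward(grad):
            return (grad @ other.data.T, self.data.T @ grad)

        out._backward = backward
        return out

    # -- reductions and shape ------------------------------------------------

    def sum(self):
        out = Tensor(self.data.sum(), parents=(self,))
        out._backward = lambda grad: (np.broadcast_to(grad, self.shape).copy(),)
        return out

    def mean(self):
        size = self.data.size
        out = Tensor(self.data.mean(), parents=(self,))
        out._backward = lambda grad: (np.broadcast_to(grad / size, self.shape).copy(),)
        return out

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), parents=(self,))
        out._backward = lambda grad: (grad.reshape(self.shape),)
        return out

    def pick(self, index: int) -> "Tensor":
        """Select one element of a flat vector (differentiable gather)."""
        out = Tensor(self.data[index], parents=(self,))

        def backward(grad):
            g = np.zeros_like(self.data)
            g[index] = grad
            return (g,)

        out._backward = backward
        return out

    # -- nonlinearities -------------------------------------------------------

    def exp(self):
        value = np.exp(self.data)
        out = Tensor(value, parents=(self,))
        out._backward = lambda grad: (grad * value,)
        return out

    def log(self):
        out = Tensor(np.log(self.data), parents=(self,))
        out._backward = lambda grad: (grad / self.data,)
        return out

    def sigmoid(self):
        value = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(value, parents=(self,))
        out._backward = lambda grad: (grad * value * (1 - value),)
        return out

    def tanh(self):
        value = np.tanh(self.data)
        out = Tensor(value, parents=(self,))
        out._backward = lambda grad: (grad * (1 - value ** 2),)
        return out

    def selu(self):
        positive = self.data > 0
        value = _SELU_SCALE * np.where(
            positive, self.data, _SELU_ALPHA * (np.exp(self.data) - 1.0))
        out = Tensor(value, parents=(self,))

        def backward(grad):
            local = _SELU_SCALE * np.where(
                positive, 1.0, _SELU_ALPHA * np.exp(self.data))
            return (grad * local,)

        out._backward = backward
        return out

    def log_softmax(self):
        """Stable log-softmax over a flat vector; -inf entries stay masked."""
        x = self.data
        xmax = np.max(x)
        shifted = x - xmax
        lse = np.log(np.sum(np.exp(shifted)))
        value = shifted - lse
        out = Tensor(value, parents=(self,))

        def backward(grad):
            softmax = np.exp(value)
            return (grad - softmax * grad.sum(),)

        out._backward = backward
        return out

    # -- autodiff driver ------------------------------------------------------

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for parent in node._parents:
                stack.append((parent, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is None or node.grad is None:
                continue
            for parent, pgrad in zip(node._parents, node._backward(node.grad)):
                if not parent.requires_grad:
                    continue
                if parent.grad is None:
                    parent.grad = np.array(pgrad, dtype=np.float64)
                else:
                    parent.grad = parent.grad + pgrad


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._wrap(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(grad):
        return tuple(np.split(grad, splits, axis=axis))

    out._backward = backward
    return out


def pad_rows(tensor: Tensor, total_rows: int) -> Tensor:
    """Zero-pad a (n, k) tensor to (total_rows, k); gradient drops the pad."""
    n, k = tensor.shape
    padded = np.zeros((total_rows, k))
    padded[:n] = tensor.data
    out = Tensor(padded, parents=(tensor,))
    out._backward = lambda grad: (grad[:n],)
    return out


# ---------------------------------------------------------------------------
# Modules
# ---------------------------------------------------------------------------

class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def uniform_init(rng: np.random.Generator, fan_in: int, shape) -> Array:
    bound = 1.0 / math.sqrt(max(fan_in, 1))
    return rng.uniform(-bound, bound, size=shape)


class Module:
    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        for value in self.__dict__.values():
            if isinstance(value, Parameter):
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Parameter):
                        params.append(item)
        return params

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_arrays(self) -> list[Array]:
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays: Iterable[Array]) -> None:
        params = self.parameters()
        arrays = list(arrays)
        if len(arrays) != len(params):
            raise ValueError("state array count mismatch")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError("state array shape mismatch")
            p.data = np.array(a, dtype=np.float64)


class Linear(Module):
    def __init__(self, rng: np.random.Generator, in_dim: int, out_dim: int):
        self.weight = Parameter(uniform_init(rng, in_dim, (in_dim, out_dim)))
        self.bias = Parameter(uniform_init(rng, in_dim, (out_dim,)))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class MLP(Module):
    """SELU feed-forward stack: `depth` linear layers, last one unactivated."""

    def __init__(self, rng: np.random.Generator, in_dim: int, hidden_dim: int,
                 out_dim: int, depth: int):
        if depth < 1:
            raise ValueError("MLP depth must be >= 1")
        dims = [in_dim] + [hidden_dim] * (depth - 1) + [out_dim]
        self.layers = [Linear(rng, dims[k], dims[k + 1]) for k in range(depth)]

    def __call__(self, x: Tensor) -> Tensor:
        for layer in self.layers[:-1]:
            x = layer(x).selu()
        return self.layers[-1](x)


class GRUCell(Module):
    """Gated recurrent update applied row-wise to node hidden states."""

    def __init__(self, rng: np.random.Generator, input_dim: int, hidden_dim: int):
        self.w_z = Linear(rng, input_dim, hidden_dim)
        self.u_z = Linear(rng, hidden_dim, hidden_dim)
        self.w_r = Linear(rng, input_dim, hidden_dim)
        self.u_r = Linear(rng, hidden_dim, hidden_dim)
        self.w_h = Linear(rng, input_dim, hidden_dim)
        self.u_h = Linear(rng, hidden_dim, hidden_dim)

    def __call__(self, message: Tensor, hidden: Tensor) -> Tensor:
        z = (self.w_z(message) + self.u_z(hidden)).sigmoid()
        r = (self.w_r(message) + self.u_r(hidden)).sigmoid()
        candidate = (self.w_h(message) + self.u_h(r * hidden)).tanh()
        return (1.0 - z) * hidden + z * candidate


class Adam:
    """Adam with a step-wise multiplicative learning-rate schedule.

    The effective rate is ``base_lr * clamp(decay^(step // interval),
    min_rel, max_rel)`` so after 20 steps with interval 10 and decay 0.99 the
    relative rate is 0.99².
    """

    def __init__(self, params: Sequence[Parameter], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0, decay_factor: float = 0.99,
                 decay_interval: int = 10, min_rel_lr: float = 1e-4,
                 max_rel_lr: float = 1.0):
        self.params = list(params)
        self.base_lr = lr
        self.betas = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.decay_factor = decay_factor
        self.decay_interval = decay_interval
        self.min_rel_lr = min_rel_lr
        self.max_rel_lr = max_rel_lr
        self.step_count = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    @property
    def lr(self) -> float:
        rel = self.decay_factor ** (self.step_count // self.decay_interval)
        rel = min(max(rel, self.min_rel_lr), self.max_rel_lr)
        return self.base_lr * rel

    def step(self) -> None:
        lr = self.lr
        self.step_count += 1
        b1, b2 = self.betas
        t = self.step_count
        for k, p in enumerate(self.params):
            if p.grad is None:
                continue
            grad = p.grad
            if self.weight_decay:
                grad = grad + self.weight_decay * p.data
            self._m[k] = b1 * self._m[k] + (1 - b1) * grad
            self._v[k] = b2 * self._v[k] + (1 - b2) * grad ** 2
            m_hat = self._m[k] / (1 - b1 ** t)
            v_hat = self._v[k] / (1 - b2 ** t)
            p.data = p.data - lr * m_hat / (np.sqrt(v_hat) + self.eps)
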