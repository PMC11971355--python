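"""Minimal reverse-mode automatic differentiation on numpy arrays.

This module provides the tensor engine and neural-network building blocks
(linear layers, embeddings, LSTM cells, multi-head attention, layer
normalization, dropout, Adam) used by the methylation classifier.  It is a
small, dependency-free tape-based engine: every operation records a closure
that accumulates gradients into its parents, and :meth:`Tensor.backward`
replays the tape in reverse topological order.

All computation is float64.  Shapes are kept modest (batches of k-mer
feature matrices), so clarity is preferred over micro-optimization.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "concat",
    "stack",
    "softmax",
    "log_softmax",
    "cross_entropy",
    "dropout",
    "Linear",
    "Embedding",
    "LayerNorm",
    "LSTM",
    "BiLSTM",
    "MultiHeadAttention",
    "TransformerEncoderLayer",
    "Adam",
    "clip_grad_norm",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` over axes that were broadcast up from ``shape``."""
    if grad.shape == shape:
        return grad
    # sum leading extra axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in parents)
        self._parents = tuple(parents)
        self._backward = backward

    # -- bookkeeping ------------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self) -> None:
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [self]
        # iterative DFS post-order (graphs can be deep for long sequences)
        while stack:
            node = stack[-1]
            if id(node) in seen:
                stack.pop()
                continue
            unvisited = [p for p in node._parents if id(p) not in seen]
            if unvisited:
                stack.extend(unvisited)
            else:
                seen.add(id(node))
                topo.append(node)
                stack.pop()
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic -------------------------------------------------------

    def __add__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))

        out._backward = backward
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape))

        out._backward = backward
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * -1.0

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __truediv__(self, other):
        return self * as_tensor(other) ** -1.0

    def __rtruediv__(self, other):
        return as_tensor(other) * self ** -1.0

    def __pow__(self, exponent: float):
        out = Tensor(self.data ** exponent, parents=(self,))

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * exponent * self.data ** (exponent - 1.0))

        out._backward = backward
        return out

    def __matmul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data @ other.data, parents=(self, other))

        def backward(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accumulate(_unbroadcast(ga, self.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accumulate(_unbroadcast(gb, other.shape))

        out._backward = backward
        return out

    # -- elementwise nonlinearities --------------------------------------

    def exp(self):
        out = Tensor(np.exp(self.data), parents=(self,))

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * out.data)

        out._backward = backward
        return out

    def log(self):
        out = Tensor(np.log(self.data), parents=(self,))

        def backward(g):
            if self.requires_grad:
                self._accumulate(g / self.data)

        out._backward = backward
        return out

    def tanh(self):
        out = Tensor(np.tanh(self.data), parents=(self,))

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * (1.0 - out.data ** 2))

        out._backward = backward
        return out

    def sigmoid(self):
        out = Tensor(1.0 / (1.0 + np.exp(-self.data)), parents=(self,))

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * out.data * (1.0 - out.data))

        out._backward = backward
        return out

    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0), parents=(self,))

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * (self.data > 0.0))

        out._backward = backward
        return out

    def sqrt(self):
        return self ** 0.5

    # -- reductions & shape ops ------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))

        def backward(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.shape).copy())
                return
            if not keepdims:
                axes = axis if isinstance(axis, tuple) else (axis,)
                g = np.expand_dims(g, tuple(a % self.ndim for a in axes))
            self._accumulate(np.broadcast_to(g, self.shape).copy())

        out._backward = backward
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), parents=(self,))

        def backward(g):
            if self.requires_grad:
                self._accumulate(g.reshape(self.shape))

        out._backward = backward
        return out

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        out = Tensor(self.data.transpose(axes), parents=(self,))
        inv = tuple(np.argsort(axes))

        def backward(g):
            if self.requires_grad:
                self._accumulate(g.transpose(inv))

        out._backward = backward
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], parents=(self,))

        def backward(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accumulate(full)

        out._backward = backward
        return out

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors, axis: int = -1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), parents=tuple(tensors))
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accumulate(g[tuple(sl)])

    out._backward = backward
    return out


def stack(tensors, axis: int = 1) -> Tensor:
    expanded = []
    for t in tensors:
        shape = list(t.shape)
        shape.insert(axis % (t.ndim + 1), 1)
        expanded.append(t.reshape(*shape))
    return concat(expanded, axis=axis)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    y = e / e.sum(axis=axis, keepdims=True)
    out = Tensor(y, parents=(x,))

    def backward(g):
        if x.requires_grad:
            dot = (g * y).sum(axis=axis, keepdims=True)
            x._accumulate(y * (g - dot))

    out._backward = backward
    return out


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x.data - x.data.max(axis=axis, keepdims=True)
    lse = np.log(np.exp(shifted).sum(axis=axis, keepdims=True))
    out = Tensor(shifted - lse, parents=(x,))
    sm = np.exp(shifted - lse)

    def backward(g):
        if x.requires_grad:
            x._accumulate(g - sm * g.sum(axis=axis, keepdims=True))

    out._backward = backward
    return out


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean negative log-likelihood of integer ``labels`` under ``logits``."""
    labels = np.asarray(labels, dtype=np.intp)
    logp = log_softmax(logits, axis=-1)
    picked = logp[np.arange(labels.shape[0]), labels]
    return -picked.mean()


def dropout(x: Tensor, rate: float, rng: np.random.Generator, training: bool) -> Tensor:
    if not training or rate <= 0.0:
        return x
    mask = (rng.random(x.shape) >= rate) / (1.0 - rate)
    return x * Tensor(mask)


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------


class Module:
    """Base class: parameter collection via attributes, recursively."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for value in self.__dict__.values():
            if isinstance(value, Tensor) and value.requires_grad:
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Tensor) and item.requires_grad:
                        params.append(item)
        return params


def _xavier(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> Tensor:
    bound = np.sqrt(6.0 / (fan_in + fan_out))
    return Tensor(rng.uniform(-bound, bound, size=shape), requires_grad=True)


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        self.weight = _xavier(rng, d_in, d_out, (d_in, d_out))
        self.bias = Tensor(np.zeros(d_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Embedding(Module):
    def __init__(self, n_symbols: int, dim: int, rng: np.random.Generator):
        self.weight = Tensor(rng.normal(0.0, 0.1, size=(n_symbols, dim)), requires_grad=True)

    def __call__(self, idx: np.ndarray) -> Tensor:
        return self.weight[np.asarray(idx, dtype=np.intp)]


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered ** 2.0).mean(axis=-1, keepdims=True)
        return centered * (var + self.eps) ** -0.5 * self.gamma + self.beta


class LSTM(Module):
    """Single-direction LSTM over (batch, time, features) input.

    Forget-gate bias initialized to 1 (standard remedy against early
    vanishing memory).
    """

    def __init__(self, d_in: int, d_hidden: int, rng: np.random.Generator):
        self.d_hidden = d_hidden
        self.w_x = _xavier(rng, d_in, 4 * d_hidden, (d_in, 4 * d_hidden))
        self.w_h = _xavier(rng, d_hidden, 4 * d_hidden, (d_hidden, 4 * d_hidden))
        bias = np.zeros(4 * d_hidden)
        bias[d_hidden:2 * d_hidden] = 1.0
        self.bias = Tensor(bias, requires_grad=True)

    def __call__(self, x: Tensor, reverse: bool = False):
        batch, steps, _ = x.shape
        h_dim = self.d_hidden
        h = Tensor(np.zeros((batch, h_dim)))
        c = Tensor(np.zeros((batch, h_dim)))
        order = range(steps - 1, -1, -1) if reverse else range(steps)
        outputs: list[Tensor] = [None] * steps  # type: ignore[list-item]
        for t in order:
            gates = x[:, t, :] @ self.w_x + h @ self.w_h + self.bias
            i = gates[:, 0:h_dim].sigmoid()
            f = gates[:, h_dim:2 * h_dim].sigmoid()
            g = gates[:, 2 * h_dim:3 * h_dim].tanh()
            o = gates[:, 3 * h_dim:4 * h_dim].sigmoid()
            c = f * c + i * g
            h = o * c.tanh()
            outputs[t] = h
        return stack(outputs, axis=1), h


class BiLSTM(Module):
    """Bidirectional LSTM: concatenated per-position outputs and final states."""

    def __init__(self, d_in: int, d_hidden: int, rng: np.random.Generator):
        self.forward_cell = LSTM(d_in, d_hidden, rng)
        self.backward_cell = LSTM(d_in, d_hidden, rng)

    def __call__(self, x: Tensor):
        out_f, last_f = self.forward_cell(x)
        out_b, last_b = self.backward_cell(x, reverse=True)
        return concat([out_f, out_b], axis=-1), (last_f, last_b)


class MultiHeadAttention(Module):
    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator):
        if dim % n_heads:
            raise ValueError(f"dim {dim} not divisible by n_heads {n_heads}")
        self.n_heads = n_heads
        self.d_head = dim // n_heads
        self.w_q = Linear(dim, dim, rng)
        self.w_k = Linear(dim, dim, rng)
        self.w_v = Linear(dim, dim, rng)
        self.w_o = Linear(dim, dim, rng)

    def _split(self, x: Tensor, batch: int, steps: int) -> Tensor:
        return x.reshape(batch, steps, self.n_heads, self.d_head).transpose(0, 2, 1, 3)

    def __call__(self, x: Tensor) -> Tensor:
        batch, steps, dim = x.shape
        q = self._split(self.w_q(x), batch, steps)
        k = self._split(self.w_k(x), batch, steps)
        v = self._split(self.w_v(x), batch, steps)
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(self.d_head))
        attn = softmax(scores, axis=-1)
        ctx = (attn @ v).transpose(0, 2, 1, 3).reshape(batch, steps, dim)
        return self.w_o(ctx)


class TransformerEncoderLayer(Module):
    """Pre-classifier BERT-style block: MHA and FFN, each with residual + LayerNorm."""

    def __init__(self, dim: int, n_heads: int, d_ff: int, dropout_rate: float,
                 rng: np.random.Generator):
        self.attn = MultiHeadAttention(dim, n_heads, rng)
        self.norm1 = LayerNorm(dim)
        self.ff1 = Linear(dim, d_ff, rng)
        self.ff2 = Linear(d_ff, dim, rng)
        self.norm2 = LayerNorm(dim)
        self.dropout_rate = dropout_rate

    def __call__(self, x: Tensor, rng: np.random.Generator, training: bool) -> Tensor:
        a = dropout(self.attn(x), self.dropout_rate, rng, training)
        x = self.norm1(x + a)
        f = dropout(self.ff2(self.ff1(x).relu()), self.dropout_rate, rng, training)
        return self.norm2(x + f)


# ---------------------------------------------------------------------------
# optimization
# ---------------------------------------------------------------------------


def clip_grad_norm(params: list[Tensor], max_norm: float) -> float:
    """Scale gradients in place so their global L2 norm is at most ``max_norm``."""
    total = 0.0
    for p in params:
        if p.grad is not None:
            total += float((p.grad ** 2).sum())
    norm = np.sqrt(total)
    if norm > max_norm and norm > 0.0:
        scale = max_norm / norm
        for p in params:
            if p.grad is not None:
                p.grad *= scale
    return norm


class Adam:
    """Adam optimizer with the standard bias-corrected moment estimates."""

    def __init__(self, params: list[Tensor], beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.params = params
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self, lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad ** 2
            m_hat = m / (1 - b1 ** self.t)
            v_hat = v / (1 - b2 ** self.t)
            p.data -= lr * m_hat / (np.sqrt(v_hat) + self.eps)
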