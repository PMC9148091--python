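"""Minimal reverse-mode automatic differentiation on numpy arrays.

Provides exactly the operations the transformer encoder and the
classification heads need: broadcast-aware arithmetic, batched matmul,
tanh/gelu, softmax, layer normalization, embedding lookup, dropout, and a
fused softmax cross-entropy with an ignore index. Training uses AdamW with
a linear warmup/decay schedule.

Deliberately small: float32 throughout, single-threaded determinism.
Graphs are single-use — backward() tears its graph down — and the no_grad
context skips graph construction entirely for inference.
"""

from __future__ import annotations

import math
from contextlib import contextmanager
from typing import Callable, Optional, Sequence

import numpy as np

_GRAD_ENABLED = [True]


@contextmanager
def no_grad():
    """Disable graph construction (inference mode).

    Outputs created inside the block carry no backward closures or parent
    references, so activations are freed as soon as they go out of scope.
    """
    _GRAD_ENABLED.append(False)
    try:
        yield
    finally:
        _GRAD_ENABLED.pop()


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum grad over broadcast dimensions so it matches `shape`."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for i, s in enumerate(shape):
        if s == 1 and grad.shape[i] != 1:
            grad = grad.sum(axis=i, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        _prev: Sequence["Tensor"] = (),
    ):
        if not _GRAD_ENABLED[-1]:
            requires_grad = False
            _prev = ()
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = requires_grad
        self._backward: Optional[Callable[[], None]] = None
        self._prev: tuple["Tensor", ...] = tuple(_prev)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    def _attach(self, backward: Callable[[], None]) -> None:
        # closures reference this tensor (a cycle); only build them when a
        # gradient can actually flow
        if self.requires_grad:
            self._backward = backward

    # -- operations ------------------------------------------------------

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other) -> "Tensor":
        other = self._wrap(other)
        out = Tensor(
            self.data + other.data,
            self.requires_grad or other.requires_grad,
            (self, other),
        )

        def backward():
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(out.grad, other.data.shape))

        out._attach(backward)
        return out

    __radd__ = __add__

    def __mul__(self, other) -> "Tensor":
        other = self._wrap(other)
        out = Tensor(
            self.data * other.data,
            self.requires_grad or other.requires_grad,
            (self, other),
        )

        def backward():
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(out.grad * self.data, other.data.shape))

        out._attach(backward)
        return out

    __rmul__ = __mul__

    def __neg__(self) -> "Tensor":
        return self * -1.0

    def __sub__(self, other) -> "Tensor":
        return self + (-self._wrap(other))

    def __truediv__(self, scalar: float) -> "Tensor":
        return self * (1.0 / scalar)

    def matmul(self, other: "Tensor") -> "Tensor":
        out = Tensor(
            np.matmul(self.data, other.data),
            self.requires_grad or other.requires_grad,
            (self, other),
        )

        def backward():
            if self.requires_grad:
                g = np.matmul(out.grad, np.swapaxes(other.data, -1, -2))
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                g = np.matmul(np.swapaxes(self.data, -1, -2), out.grad)
                other._accum(_unbroadcast(g, other.data.shape))

        out._attach(backward)
        return out

    __matmul__ = matmul

    def reshape(self, *shape: int) -> "Tensor":
        out = Tensor(self.data.reshape(shape), self.requires_grad, (self,))

        def backward():
            if self.requires_grad:
                self._accum(out.grad.reshape(self.data.shape))

        out._attach(backward)
        return out

    def swapaxes(self, a: int, b: int) -> "Tensor":
        out = Tensor(np.swapaxes(self.data, a, b), self.requires_grad, (self,))

        def backward():
            if self.requires_grad:
                self._accum(np.swapaxes(out.grad, a, b))

        out._attach(backward)
        return out

    def tanh(self) -> "Tensor":
        y = np.tanh(self.data)
        out = Tensor(y, self.requires_grad, (self,))

        def backward():
            if self.requires_grad:
                self._accum(out.grad * (1.0 - y * y))

        out._attach(backward)
        return out

    def gelu(self) -> "Tensor":
        # tanh approximation, as in the original encoder implementations
        x = self.data
        c = math.sqrt(2.0 / math.pi)
        inner = c * (x + 0.044715 * x**3)
        t = np.tanh(inner)
        y = 0.5 * x * (1.0 + t)
        out = Tensor(y, self.requires_grad, (self,))

        def backward():
            if self.requires_grad:
                dinner = c * (1.0 + 3 * 0.044715 * x**2)
                dy = 0.5 * (1.0 + t) + 0.5 * x * (1.0 - t * t) * dinner
                self._accum(out.grad * dy)

        out._attach(backward)
        return out

    def softmax(self, axis: int = -1) -> "Tensor":
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        y = e / e.sum(axis=axis, keepdims=True)
        out = Tensor(y, self.requires_grad, (self,))

        def backward():
            if self.requires_grad:
                g = out.grad
                dot = (g * y).sum(axis=axis, keepdims=True)
                self._accum(y * (g - dot))

        out._attach(backward)
        return out

    def mean(self) -> "Tensor":
        out = Tensor(self.data.mean(), self.requires_grad, (self,))

        def backward():
            if self.requires_grad:
                self._accum(
                    np.full(self.data.shape, out.grad / self.data.size, np.float32)
                )

        out._attach(backward)
        return out

    def layer_norm(self, gain: "Tensor", bias: "Tensor", eps: float = 1e-12) -> "Tensor":
        """Normalize the last axis, then scale and shift."""
        mu = self.data.mean(axis=-1, keepdims=True)
        var = self.data.var(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + eps)
        xhat = (self.data - mu) * inv
        out = Tensor(
            xhat * gain.data + bias.data,
            self.requires_grad or gain.requires_grad or bias.requires_grad,
            (self, gain, bias),
        )

        def backward():
            g = out.grad
            if gain.requires_grad:
                gain._accum((g * xhat).reshape(-1, xhat.shape[-1]).sum(axis=0))
            if bias.requires_grad:
                bias._accum(g.reshape(-1, xhat.shape[-1]).sum(axis=0))
            if self.requires_grad:
                gx = g * gain.data
                term = gx - gx.mean(axis=-1, keepdims=True) - xhat * (
                    gx * xhat
                ).mean(axis=-1, keepdims=True)
                self._accum(term * inv)

        out._attach(backward)
        return out

    def dropout(self, rate: float, rng: np.random.Generator) -> "Tensor":
        if rate <= 0.0:
            return self
        keep = (rng.random(self.data.shape) >= rate).astype(np.float32)
        scale = 1.0 / (1.0 - rate)
        out = Tensor(self.data * keep * scale, self.requires_grad, (self,))

        def backward():
            if self.requires_grad:
                self._accum(out.grad * keep * scale)

        out._attach(backward)
        return out

    def concat(self, other: "Tensor", axis: int = -1) -> "Tensor":
        out = Tensor(
            np.concatenate([self.data, other.data], axis=axis),
            self.requires_grad or other.requires_grad,
            (self, other),
        )
        split = self.data.shape[axis]

        def backward():
            g1, g2 = np.split(out.grad, [split], axis=axis)
            if self.requires_grad:
                self._accum(g1)
            if other.requires_grad:
                other._accum(g2)

        out._attach(backward)
        return out

    def take_rows(self, indices: np.ndarray) -> "Tensor":
        """Gather rows of a 2-D tensor: (N, H) -> (len(indices), H)."""
        out = Tensor(self.data[indices], self.requires_grad, (self,))

        def backward():
            if self.requires_grad:
                g = np.zeros_like(self.data)
                np.add.at(g, indices, out.grad)
                self._accum(g)

        out._attach(backward)
        return out

    def take_position(self, pos: int) -> "Tensor":
        """Select one sequence position: (B, T, H) -> (B, H)."""
        out = Tensor(self.data[:, pos, :], self.requires_grad, (self,))

        def backward():
            if self.requires_grad:
                g = np.zeros_like(self.data)
                g[:, pos, :] = out.grad
                self._accum(g)

        out._attach(backward)
        return out

    # -- backprop driver ------------------------------------------------

    def backward(self) -> None:
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
            for p in node._prev:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward()
        # the graph is single-use: break the closure cycles so refcounting
        # can reclaim the activations immediately
        for node in topo:
            node._backward = None
            node._prev = ()


def embedding_lookup(table: Tensor, ids: np.ndarray) -> Tensor:
    """Row gather: table (V, H), ids int array (...,) -> (..., H)."""
    out = Tensor(table.data[ids], table.requires_grad, (table,))

    def backward():
        if table.requires_grad:
            g = np.zeros_like(table.data)
            np.add.at(g, ids.reshape(-1), out.grad.reshape(-1, table.data.shape[1]))
            table._accum(g)

    out._attach(backward)
    return out


def cross_entropy(logits: Tensor, targets: np.ndarray, ignore_index: int = -100) -> Tensor:
    """Mean softmax cross-entropy over rows whose target != ignore_index.

    logits: (N, C); targets: (N,) int. If every target is ignored the loss
    is 0 with zero gradient.
    """
    z = logits.data - logits.data.max(axis=-1, keepdims=True)
    logsumexp = np.log(np.exp(z).sum(axis=-1))
    valid = targets != ignore_index
    n_valid = int(valid.sum())
    safe_t = np.where(valid, targets, 0)
    nll = logsumexp - z[np.arange(len(targets)), safe_t]
    loss_val = float(nll[valid].mean()) if n_valid else 0.0
    out = Tensor(loss_val, logits.requires_grad, (logits,))

    def backward():
        if logits.requires_grad and n_valid:
            p = np.exp(z) / np.exp(z).sum(axis=-1, keepdims=True)
            p[np.arange(len(targets)), safe_t] -= 1.0
            p[~valid] = 0.0
            logits._accum(p * (out.grad / n_valid))

    out._attach(backward)
    return out


# ---------------------------------------------------------------------------
# Parameters, modules, optimizer
# ---------------------------------------------------------------------------


class Module:
    """Base class tracking named parameters recursively."""

    def parameters(self) -> dict[str, Tensor]:
        params: dict[str, Tensor] = {}
        for name, val in vars(self).items():
            if isinstance(val, Tensor) and val.requires_grad:
                params[name] = val
            elif isinstance(val, Module):
                for sub, p in val.parameters().items():
                    params[f"{name}.{sub}"] = p
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        for sub, p in item.parameters().items():
                            params[f"{name}.{i}.{sub}"] = p
        return params

    def zero_grad(self) -> None:
        for p in self.parameters().values():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.parameters().items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.parameters()
        missing = set(params) - set(state)
        if missing:
            raise KeyError(f"missing parameters in state dict: {sorted(missing)}")
        for k, p in params.items():
            p.data[...] = state[k]


class Linear(Module):
    """Dense layer; init_std=None selects Glorot (for stand-alone tanh MLPs),
    a fixed std (0.02 by convention) suits transformer-internal layers."""

    def __init__(
        self,
        d_in: int,
        d_out: int,
        rng: np.random.Generator,
        init_std: Optional[float] = 0.02,
    ):
        std = math.sqrt(2.0 / (d_in + d_out)) if init_std is None else init_std
        self.weight = Tensor(
            rng.normal(0.0, std, (d_in, d_out)), requires_grad=True
        )
        self.bias = Tensor(np.zeros(d_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class LayerNorm(Module):
    def __init__(self, dim: int):
        self.gain = Tensor(np.ones(dim), requires_grad=True)
        self.bias = Tensor(np.zeros(dim), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x.layer_norm(self.gain, self.bias)


class AdamW:
    """Adam with decoupled weight decay and linear warmup/decay schedule.

    Weight decay is applied only to matrices (ndim >= 2), matching the usual
    encoder fine-tuning recipe that exempts biases and layer-norm gains.
    """

    def __init__(
        self,
        params: dict[str, Tensor],
        lr: float,
        total_steps: int,
        warmup_frac: float = 0.1,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 0.01,
    ):
        self.params = params
        self.base_lr = lr
        self.total_steps = max(1, total_steps)
        self.warmup_steps = max(1, int(warmup_frac * self.total_steps))
        self.betas = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def current_lr(self) -> float:
        t = self.t
        if t < self.warmup_steps:
            return self.base_lr * (t + 1) / self.warmup_steps
        frac = (self.total_steps - t) / max(1, self.total_steps - self.warmup_steps)
        return self.base_lr * max(0.0, frac)

    def step(self) -> None:
        lr = self.current_lr()
        b1, b2 = self.betas
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            update = mhat / (np.sqrt(vhat) + self.eps)
            if self.weight_decay and p.data.ndim >= 2:
                update = update + self.weight_decay * p.data
            p.data -= lr * update
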