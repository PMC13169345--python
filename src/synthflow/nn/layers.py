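"""Neural-network building blocks on top of the autodiff core."""

from __future__ import annotations

from typing import Iterable

import numpy as np

from .autodiff import Tensor, concat, log_softmax, softmax

__all__ = [
    "Module",
    "Linear",
    "Embedding",
    "LayerNorm",
    "MaskedBatchNorm",
    "Dropout",
    "MLP",
    "Adam",
    "cross_entropy_logits",
]


class Module:
    """Base class: anything exposing trainable :class:`Tensor` leaves."""

    def parameters(self) -> list[Tensor]:
        out: list[Tensor] = []
        for v in vars(self).values():
            if isinstance(v, Tensor) and v.requires_grad:
                out.append(v)
            elif isinstance(v, Module):
                out.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.parameters())
                    elif isinstance(item, Tensor) and item.requires_grad:
                        out.append(item)
        return out

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays: Iterable[np.ndarray]) -> None:
        params = self.parameters()
        arrays = list(arrays)
        if len(arrays) != len(params):
            raise ValueError(
                f"checkpoint has {len(arrays)} arrays, model has {len(params)}"
            )
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError(f"shape mismatch {p.data.shape} vs {a.shape}")
            p.data = np.asarray(a, dtype=np.float64)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    # training-mode flag consumed by Dropout / MaskedBatchNorm
    training: bool = True

    def train(self) -> None:
        self.training = True
        for v in vars(self).values():
            if isinstance(v, Module):
                v.train()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        item.train()

    def eval(self) -> None:
        self.training = False
        for v in vars(self).values():
            if isinstance(v, Module):
                v.eval()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        item.eval()


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> np.ndarray:
    lim = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-lim, lim, size=shape)


class Linear(Module):
    def __init__(self, rng: np.random.Generator, n_in: int, n_out: int, bias: bool = True):
        self.w = Tensor(_glorot(rng, n_in, n_out, (n_in, n_out)), requires_grad=True)
        self.b = Tensor(np.zeros(n_out), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        y = x @ self.w
        if self.b is not None:
            y = y + self.b
        return y


class Embedding(Module):
    def __init__(self, rng: np.random.Generator, n_vocab: int, dim: int):
        self.w = Tensor(rng.normal(0.0, 0.02, size=(n_vocab, dim)), requires_grad=True)

    def __call__(self, idx: np.ndarray) -> Tensor:
        return self.w[np.asarray(idx, dtype=np.int64)]


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        inv = (var + self.eps) ** -0.5
        return xc * inv * self.gamma + self.beta


class MaskedBatchNorm(Module):
    """Batch normalization over the valid positions of a padded batch.

    Statistics are taken over every unmasked row across the whole batch
    (for graphs: every real atom of every molecule), which keeps the
    layer invariant to node ordering.
    """

    def __init__(self, dim: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.running_mean = np.zeros(dim)
        self.running_var = np.ones(dim)
        self.momentum = momentum
        self.eps = eps

    def __call__(self, x: Tensor, mask: np.ndarray | None = None) -> Tensor:
        # x: (..., dim); mask broadcasts over the leading axes, True = valid
        if self.training:
            if mask is None:
                w = np.ones(x.shape[:-1])
            else:
                w = mask.astype(np.float64)
            n = max(w.sum(), 1.0)
            wt = Tensor(np.expand_dims(w / n, -1))
            mu = (x * wt).sum(axis=tuple(range(x.ndim - 1)))
            xc = x - mu
            var = (xc * xc * wt).sum(axis=tuple(range(x.ndim - 1)))
            self.running_mean = (
                (1 - self.momentum) * self.running_mean + self.momentum * mu.data
            )
            self.running_var = (
                (1 - self.momentum) * self.running_var + self.momentum * var.data
            )
        else:
            mu = Tensor(self.running_mean)
            var = Tensor(self.running_var)
            xc = x - mu
        inv = (var + self.eps) ** -0.5
        return xc * inv * self.gamma + self.beta


class Dropout(Module):
    def __init__(self, p: float, rng: np.random.Generator):
        self.p = p
        self.rng = rng

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.p <= 0.0:
            return x
        keep = self.rng.random(x.shape) >= self.p
        return x * Tensor(keep / (1.0 - self.p))


class MLP(Module):
    """Plain fully connected stack with ReLU between hidden layers."""

    def __init__(self, rng, n_in: int, hidden: list[int], n_out: int):
        dims = [n_in, *hidden, n_out]
        self.layers = [Linear(rng, a, b) for a, b in zip(dims[:-1], dims[1:])]

    def __call__(self, x: Tensor) -> Tensor:
        for i, layer in enumerate(self.layers):
            x = layer(x)
            if i < len(self.layers) - 1:
                x = x.relu()
        return x


def cross_entropy_logits(
    logits: Tensor, targets: np.ndarray, weight: np.ndarray | None = None
) -> Tensor:
    """Mean negative log-likelihood of integer targets under ``logits``.

    ``weight`` (same shape as ``targets``) zeroes out padding positions.
    """
    logp = log_softmax(logits, axis=-1)
    idx = tuple(np.indices(targets.shape)) + (targets,)
    nll = -logp[idx]
    if weight is None:
        return nll.mean()
    w = np.asarray(weight, dtype=np.float64)
    return (nll * Tensor(w)).sum() * (1.0 / max(w.sum(), 1.0))


class Adam:
    """Adam with optional global gradient-norm clipping."""

    def __init__(
        self,
        params: list[Tensor],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        clip_norm: float | None = None,
    ):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.clip_norm = clip_norm
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        self.t += 1
        grads = [
            p.grad if p.grad is not None else np.zeros_like(p.data)
            for p in self.params
        ]
        if self.clip_norm is not None:
            total = np.sqrt(sum(float((g * g).sum()) for g in grads))
            if total > self.clip_norm:
                scale = self.clip_norm / (total + 1e-12)
                grads = [g * scale for g in grads]
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
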