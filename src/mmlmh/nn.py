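"""Neural building blocks on top of the autodiff tape.

Parameter containers, linear layers, dropout, a two-layer feed-forward block
(the encoder/decoder unit used throughout the framework), single-head scaled
dot-product attention, and a decoupled-weight-decay Adam optimizer.
"""

from __future__ import annotations

from typing import Callable, Iterator

import numpy as np

from ._tensor import Tensor

__all__ = [
    "Parameter",
    "Module",
    "Linear",
    "Dropout",
    "FeedForward",
    "SelfAttention",
    "softmax",
    "AdamW",
]


class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Base class: parameter discovery and train/eval mode propagation."""

    def __init__(self):
        self.training = True

    def modules(self) -> Iterator["Module"]:
        yield self
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield from v.modules()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield from item.modules()
            elif isinstance(v, dict):
                for item in v.values():
                    if isinstance(item, Module):
                        yield from item.modules()

    def parameters(self) -> list[Parameter]:
        out: list[Parameter] = []
        for mod in self.modules():
            for v in mod.__dict__.values():
                if isinstance(v, Parameter):
                    out.append(v)
                elif isinstance(v, (list, tuple)):
                    out.extend(p for p in v if isinstance(p, Parameter))
        return out

    def named_parameters(self) -> dict[str, Parameter]:
        out: dict[str, Parameter] = {}

        def walk(mod: "Module", prefix: str):
            for k, v in mod.__dict__.items():
                name = f"{prefix}{k}"
                if isinstance(v, Parameter):
                    out[name] = v
                elif isinstance(v, Module):
                    walk(v, name + ".")
                elif isinstance(v, (list, tuple)):
                    for i, item in enumerate(v):
                        if isinstance(item, Parameter):
                            out[f"{name}.{i}"] = item
                        elif isinstance(item, Module):
                            walk(item, f"{name}.{i}.")
                elif isinstance(v, dict):
                    for key, item in v.items():
                        if isinstance(item, Parameter):
                            out[f"{name}.{key}"] = item
                        elif isinstance(item, Module):
                            walk(item, f"{name}.{key}.")

        walk(self, "")
        return out

    def train(self, mode: bool = True) -> "Module":
        for mod in self.modules():
            mod.training = mode
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.parameters()))


class Linear(Module):
    """Affine map with Glorot-uniform initialisation."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator, bias: bool = True):
        super().__init__()
        limit = np.sqrt(6.0 / (d_in + d_out))
        self.weight = Parameter(rng.uniform(-limit, limit, size=(d_in, d_out)))
        self.bias = Parameter(np.zeros(d_out)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class Dropout(Module):
    """Inverted dropout; identity in eval mode. Draws from the supplied rng."""

    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0,1): {rate}")
        self.rate = rate
        self._rng = rng

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.rate == 0.0:
            return x
        keep = 1.0 - self.rate
        mask = (self._rng.random(x.shape) < keep) / keep
        return x * mask


class FeedForward(Module):
    """Two-layer block: Linear -> activation -> Dropout -> Linear.

    The standard encoder/decoder unit of the framework (hidden width and
    dropout are configuration values).
    """

    def __init__(
        self,
        d_in: int,
        d_hidden: int,
        d_out: int,
        rng: np.random.Generator,
        dropout: float = 0.2,
        activation: str = "relu",
    ):
        super().__init__()
        self.fc1 = Linear(d_in, d_hidden, rng)
        self.fc2 = Linear(d_hidden, d_out, rng)
        self.drop = Dropout(dropout, rng)
        self._act = _ACTIVATIONS[activation]

    def __call__(self, x: Tensor) -> Tensor:
        return self.fc2(self.drop(self._act(self.fc1(x))))


_ACTIVATIONS: dict[str, Callable[[Tensor], Tensor]] = {
    "relu": lambda t: t.relu(),
    "tanh": lambda t: t.tanh(),
    "sigmoid": lambda t: t.sigmoid(),
}


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Numerically stable softmax (the constant max-shift carries no gradient)."""
    shifted = x - np.max(x.data, axis=axis, keepdims=True)
    e = shifted.exp()
    return e / e.sum(axis=axis, keepdims=True)


class SelfAttention(Module):
    """Single-head scaled dot-product attention over a token axis.

    Input (B, L, d_in) -> output (B, L, d_out); the most recent attention
    map (B, L, L) is kept on `last_attention` for diagnostics.
    """

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        super().__init__()
        self.wq = Linear(d_in, d_out, rng, bias=False)
        self.wk = Linear(d_in, d_out, rng, bias=False)
        self.wv = Linear(d_in, d_out, rng, bias=False)
        self.scale = 1.0 / np.sqrt(d_out)
        self.last_attention: np.ndarray | None = None

    def __call__(self, tokens: Tensor) -> Tensor:
        q, k, v = self.wq(tokens), self.wk(tokens), self.wv(tokens)
        logits = (q @ k.swapaxes(-1, -2)) * self.scale
        att = softmax(logits, axis=-1)
        self.last_attention = att.data.copy()
        return att @ v


class AdamW:
    """Adam with decoupled weight decay (the Table-default optimizer)."""

    def __init__(
        self,
        params: list[Parameter],
        lr: float = 1e-4,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 1e-5,
    ):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for i, p in enumerate(self.params):
            g = p.grad
            if g is None:
                continue
            self._m[i] = self.b1 * self._m[i] + (1.0 - self.b1) * g
            self._v[i] = self.b2 * self._v[i] + (1.0 - self.b2) * g**2
            m_hat = self._m[i] / b1t
            v_hat = self._v[i] / b2t
            p.data -= self.lr * (
                m_hat / (np.sqrt(v_hat) + self.eps) + self.weight_decay * p.data
            )
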