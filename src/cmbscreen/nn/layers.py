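"""Neural-network modules built on the autograd core.

Initialization is explicit: every module takes a ``numpy.random.Generator`` so
model construction is deterministic given a seed.  Parameters are float32.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from .tensor import (Tensor, adaptive_avg_pool2d, adaptive_max_pool2d, bilinear_resize,
                     concatenate, conv1d, conv2d, conv3d, softmax)

__all__ = ["Module", "ModuleList", "Sequential", "Linear", "Conv2d", "Conv3d", "Conv1d",
           "BatchNorm2d", "BatchNorm3d", "LayerNorm", "MultiHeadAttention",
           "TransformerBlock", "Activation"]


def _kaiming(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    std = np.sqrt(2.0 / fan_in)
    return (rng.standard_normal(shape) * std).astype(np.float32)


class Module:
    """Parameter container with named_parameters / state_dict plumbing."""

    def __init__(self) -> None:
        self.training = True

    def modules(self) -> Iterator["Module"]:
        yield self
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield from v.modules()

    def named_parameters(self, prefix: str = "", _seen: set | None = None
                         ) -> Iterator[tuple[str, Tensor]]:
        if _seen is None:
            _seen = set()
        for name, v in self.__dict__.items():
            full = f"{prefix}{name}"
            if isinstance(v, Tensor) and v.requires_grad:
                if id(v) not in _seen:
                    _seen.add(id(v))
                    yield full, v
            elif isinstance(v, Module):
                yield from v.named_parameters(f"{full}.", _seen)

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def num_parameters(self) -> int:
        return int(sum(p.size for p in self.parameters()))

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def train(self) -> "Module":
        for m in self.modules():
            m.training = True
        return self

    def eval(self) -> "Module":
        for m in self.modules():
            m.training = False
        return self

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        if set(params) != set(state):
            raise ValueError("state dict keys do not match module parameters")
        for k, v in state.items():
            params[k].data = np.asarray(v, dtype=params[k].data.dtype).reshape(params[k].shape)

    def checksum(self) -> float:
        """Deterministic scalar fingerprint of all parameters."""
        return float(sum(np.abs(p.data).sum() for p in self.parameters()))

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class ModuleList(Module):
    def __init__(self, mods) -> None:
        super().__init__()
        for i, m in enumerate(mods):
            setattr(self, f"m{i}", m)
        self._n = len(mods)

    def __iter__(self):
        return (getattr(self, f"m{i}") for i in range(self._n))

    def __len__(self):
        return self._n

    def __getitem__(self, i):
        return getattr(self, f"m{i}")


class Sequential(Module):
    def __init__(self, *mods) -> None:
        super().__init__()
        self.layers = ModuleList(list(mods))

    def forward(self, x):
        for m in self.layers:
            x = m(x)
        return x


class Activation(Module):
    def __init__(self, kind: str = "silu") -> None:
        super().__init__()
        self.kind = kind

    def forward(self, x: Tensor) -> Tensor:
        return getattr(x, self.kind)()


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator, bias: bool = True,
                 zero_init: bool = False) -> None:
        super().__init__()
        if zero_init:
            w = np.zeros((d_in, d_out), dtype=np.float32)
        else:
            w = _kaiming(rng, (d_in, d_out), d_in)
        self.w = Tensor(w, requires_grad=True)
        self.b = Tensor(np.zeros(d_out, dtype=np.float32), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        y = x @ self.w
        if self.b is not None:
            y = y + self.b
        return y


class Conv2d(Module):
    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator,
                 stride=1, padding=None, bias: bool = True) -> None:
        super().__init__()
        if padding is None:
            padding = k // 2
        self.stride, self.padding = stride, padding
        self.w = Tensor(_kaiming(rng, (c_out, c_in, k, k), c_in * k * k), requires_grad=True)
        self.b = Tensor(np.zeros(c_out, dtype=np.float32), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.w, self.b, stride=self.stride, padding=self.padding)


class Conv3d(Module):
    def __init__(self, c_in: int, c_out: int, k, rng: np.random.Generator,
                 stride=(1, 1, 1), padding=None, bias: bool = True) -> None:
        super().__init__()
        k = (k, k, k) if isinstance(k, int) else tuple(k)
        if padding is None:
            padding = tuple(ki // 2 for ki in k)
        self.stride, self.padding = tuple(stride), padding
        fan = c_in * int(np.prod(k))
        self.w = Tensor(_kaiming(rng, (c_out, c_in) + k, fan), requires_grad=True)
        self.b = Tensor(np.zeros(c_out, dtype=np.float32), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return conv3d(x, self.w, self.b, stride=self.stride, padding=self.padding)


class Conv1d(Module):
    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator,
                 stride: int = 1, padding=None, bias: bool = True) -> None:
        super().__init__()
        if padding is None:
            padding = k // 2
        self.stride, self.padding = stride, padding
        self.w = Tensor(_kaiming(rng, (c_out, c_in, k), c_in * k), requires_grad=True)
        self.b = Tensor(np.zeros(c_out, dtype=np.float32), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return conv1d(x, self.w, self.b, stride=self.stride, padding=self.padding)


class _BatchNorm(Module):
    """Composite batchnorm; reduction axes set by the subclass."""

    axes: tuple[int, ...]

    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5) -> None:
        super().__init__()
        self.gamma = Tensor(np.ones(c, dtype=np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(c, dtype=np.float32), requires_grad=True)
        self.momentum, self.eps = momentum, eps
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)

    def _shape(self, ndim: int) -> tuple[int, ...]:
        s = [1] * ndim
        s[1] = -1
        return tuple(s)

    def forward(self, x: Tensor) -> Tensor:
        shp = self._shape(x.ndim)
        if self.training:
            mu = x.mean(axis=self.axes, keepdims=True)
            var = ((x - mu.detach()) ** 2.0).mean(axis=self.axes, keepdims=True)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mu.data.reshape(-1))
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var.data.reshape(-1))
            xhat = (x - mu) / ((var + self.eps) ** 0.5)
        else:
            mu = Tensor(self.running_mean.reshape(shp))
            var = Tensor(self.running_var.reshape(shp))
            xhat = (x - mu) / ((var + self.eps) ** 0.5)
        return xhat * self.gamma.reshape(shp) + self.beta.reshape(shp)


class BatchNorm2d(_BatchNorm):
    axes = (0, 2, 3)


class BatchNorm3d(_BatchNorm):
    axes = (0, 2, 3, 4)


class LayerNorm(Module):
    def __init__(self, d: int, eps: float = 1e-5) -> None:
        super().__init__()
        self.gamma = Tensor(np.ones(d, dtype=np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(d, dtype=np.float32), requires_grad=True)
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        var = ((x - mu.detach()) ** 2.0).mean(axis=-1, keepdims=True)
        return (x - mu) / ((var + self.eps) ** 0.5) * self.gamma + self.beta


class MultiHeadAttention(Module):
    """Scaled dot-product attention over token sequences of shape (B, L, D).

    ``zero_init_out=True`` zero-initializes the output projection so a freshly
    inserted block leaves a residual path untouched.
    """

    def __init__(self, dim: int, heads: int, rng: np.random.Generator,
                 kv_dim: int | None = None, zero_init_out: bool = False) -> None:
        super().__init__()
        if dim % heads:
            raise ValueError(f"dim {dim} not divisible by heads {heads}")
        kv_dim = kv_dim or dim
        self.heads = heads
        self.dk = dim // heads
        self.q = Linear(dim, dim, rng)
        self.k = Linear(kv_dim, dim, rng)
        self.v = Linear(kv_dim, dim, rng)
        self.out = Linear(dim, dim, rng, zero_init=zero_init_out)
        self.last_attention: np.ndarray | None = None

    def forward(self, x_q: Tensor, x_kv: Tensor | None = None) -> Tensor:
        if x_kv is None:
            x_kv = x_q
        B, Lq, D = x_q.shape
        Lk = x_kv.shape[1]

        def split(t: Tensor, L: int) -> Tensor:
            return t.reshape(B, L, self.heads, self.dk).transpose(0, 2, 1, 3)

        q = split(self.q(x_q), Lq)
        k = split(self.k(x_kv), Lk)
        v = split(self.v(x_kv), Lk)
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(self.dk))
        attn = softmax(scores, axis=-1)
        self.last_attention = attn.data
        y = attn @ v
        y = y.transpose(0, 2, 1, 3).reshape(B, Lq, D)
        return self.out(y)


class TransformerBlock(Module):
    """Pre-LN encoder block: LN -> MHA -> residual, LN -> MLP(GELU) -> residual."""

    def __init__(self, dim: int, heads: int, rng: np.random.Generator,
                 mlp_ratio: float = 2.0) -> None:
        super().__init__()
        self.ln1 = LayerNorm(dim)
        self.attn = MultiHeadAttention(dim, heads, rng)
        self.ln2 = LayerNorm(dim)
        hidden = int(dim * mlp_ratio)
        self.fc1 = Linear(dim, hidden, rng)
        self.fc2 = Linear(hidden, dim, rng)

    def forward(self, x: Tensor) -> Tensor:
        x = x + self.attn(self.ln1(x))
        return x + self.fc2(self.fc1(self.ln2(x)).gelu())
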