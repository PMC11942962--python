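"""Neural-network building blocks on top of the autograd engine.

Initialization draws from a caller-supplied :class:`numpy.random.Generator`
so that every model in the package is reproducible from a single seed.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, concatenate

__all__ = [
    "Module",
    "Linear",
    "Embedding",
    "LayerNorm",
    "MaskedBatchNorm",
    "Conv1d",
]


class Module:
    """Base class with recursive parameter collection and train/eval mode."""

    def __init__(self):
        self.training = True

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        seen: set[int] = set()
        for value in vars(self).values():
            for p in _collect(value):
                if id(p) not in seen:
                    seen.add(id(p))
                    params.append(p)
        return params

    def modules(self) -> list["Module"]:
        mods = [self]
        for value in vars(self).values():
            mods.extend(_collect_modules(value))
        return mods

    def train(self):
        for m in self.modules():
            m.training = True
        return self

    def eval(self):
        for m in self.modules():
            m.training = False
        return self

    # -- flat state dict for checkpointing ------------------------------------
    def state_arrays(self) -> list[np.ndarray]:
        """All parameters plus persistent buffers, in deterministic order."""
        arrays = [p.data for p in self.parameters()]
        for m in self.modules():
            for name in getattr(m, "_buffers", ()):
                arrays.append(getattr(m, name))
        return arrays

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        it = iter(arrays)
        for p in self.parameters():
            a = next(it)
            if a.shape != p.data.shape:
                raise ValueError(f"shape mismatch loading checkpoint: {a.shape} vs {p.data.shape}")
            p.data = np.array(a, dtype=np.float64)
        for m in self.modules():
            for name in getattr(m, "_buffers", ()):
                setattr(m, name, np.array(next(it), dtype=np.float64))


def _collect(value):
    if isinstance(value, Tensor) and value.requires_grad:
        yield value
    elif isinstance(value, Module):
        yield from value.parameters()
    elif isinstance(value, (list, tuple)):
        for v in value:
            yield from _collect(v)
    elif isinstance(value, dict):
        for v in value.values():
            yield from _collect(v)


def _collect_modules(value):
    if isinstance(value, Module):
        yield from value.modules()
    elif isinstance(value, (list, tuple)):
        for v in value:
            yield from _collect_modules(v)
    elif isinstance(value, dict):
        for v in value.values():
            yield from _collect_modules(v)


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator, bias: bool = True):
        super().__init__()
        scale = 1.0 / np.sqrt(in_dim)
        self.weight = Tensor(rng.uniform(-scale, scale, size=(in_dim, out_dim)), requires_grad=True)
        self.bias = Tensor(np.zeros(out_dim), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class Embedding(Module):
    def __init__(self, vocab: int, dim: int, rng: np.random.Generator, scale: float = 0.02):
        super().__init__()
        self.weight = Tensor(rng.normal(0.0, scale, size=(vocab, dim)), requires_grad=True)

    def __call__(self, ids: np.ndarray) -> Tensor:
        return self.weight.take(np.asarray(ids, dtype=np.intp), axis=0)


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered**2.0).mean(axis=-1, keepdims=True)
        return centered / (var + self.eps).sqrt() * self.gamma + self.beta


class MaskedBatchNorm(Module):
    """Batch normalization over channels-last (B, L, D) sequence tensors.

    Statistics are computed over the batch and length axes jointly, but only
    at positions flagged valid by ``mask`` — padded positions neither
    contribute to the statistics nor leak between batch compositions. Running
    statistics are used in eval mode.
    """

    _buffers = ("running_mean", "running_var")

    def __init__(self, dim: int, momentum: float = 0.1, eps: float = 1e-5, affine: bool = True):
        super().__init__()
        self.affine = affine
        if affine:
            self.gamma = Tensor(np.ones(dim), requires_grad=True)
            self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.running_mean = np.zeros(dim)
        self.running_var = np.ones(dim)
        self.momentum = momentum
        self.eps = eps

    def __call__(self, x: Tensor, mask: np.ndarray) -> Tensor:
        mask3 = np.asarray(mask, dtype=np.float64)[..., None]  # (B, L, 1)
        if self.training:
            n = mask3.sum()
            m = Tensor(mask3)
            mean = (x * m).sum(axis=(0, 1)) * (1.0 / n)
            centered = x - mean
            var = ((centered**2.0) * m).sum(axis=(0, 1)) * (1.0 / n)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean.data
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var.data
            out = centered / (var + self.eps).sqrt()
        else:
            out = (x - Tensor(self.running_mean)) / Tensor(
                np.sqrt(self.running_var + self.eps)
            )
        if self.affine:
            out = out * self.gamma + self.beta
        return out * Tensor(mask3)


class Conv1d(Module):
    """1-D convolution along the length axis of a (B, L, D_in) tensor.

    Odd kernel widths with symmetric zero padding ('same'), implemented as a
    sum over kernel taps of shifted matrix products — no im2col buffers.
    """

    def __init__(
        self,
        in_dim: int,
        out_dim: int,
        kernel_size: int,
        rng: np.random.Generator,
        bias: bool = True,
    ):
        super().__init__()
        if kernel_size % 2 == 0:
            raise ValueError(f"kernel_size must be odd, got {kernel_size}")
        self.kernel_size = kernel_size
        scale = 1.0 / np.sqrt(in_dim * kernel_size)
        self.weight = Tensor(
            rng.uniform(-scale, scale, size=(kernel_size, in_dim, out_dim)),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(out_dim), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        B, L, _ = x.shape
        half = self.kernel_size // 2
        out = None
        for t in range(self.kernel_size):
            w_t = self.weight[t]
            shifted = _shift_seq(x, t - half, B, L)
            term = shifted @ w_t
            out = term if out is None else out + term
        if self.bias is not None:
            out = out + self.bias
        return out


def _shift_seq(x: Tensor, offset: int, B: int, L: int) -> Tensor:
    """Shift (B, L, D) content by ``offset`` along L with zero fill."""
    if offset == 0:
        return x
    D = x.shape[-1]
    pad = Tensor(np.zeros((B, abs(offset), D)))
    if offset > 0:
        return concatenate([x[:, offset:, :], pad], axis=1)
    return concatenate([pad, x[:, :offset, :]], axis=1)
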