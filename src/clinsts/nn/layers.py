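"""Neural-network building blocks on top of the autograd core."""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, concat

__all__ = ["Module", "Parameter", "Linear", "Embedding", "LayerNorm", "sliding_windows"]


class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Base class with recursive parameter discovery (attribute walk)."""

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def named_parameters(self, prefix: str = "") -> list[tuple[str, Parameter]]:
        out: list[tuple[str, Parameter]] = []
        for name, value in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(value, Parameter):
                out.append((key, value))
            elif isinstance(value, Module):
                out.extend(value.named_parameters(prefix=key + "."))
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        out.extend(item.named_parameters(prefix=f"{key}.{i}."))
                    elif isinstance(item, Parameter):
                        out.append((f"{key}.{i}", item))
        return out

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        if missing:
            raise KeyError(f"missing parameters in state dict: {sorted(missing)}")
        for name, p in own.items():
            arr = np.asarray(state[name], dtype=np.float64)
            if arr.shape != p.data.shape:
                raise ValueError(
                    f"shape mismatch for {name}: checkpoint {arr.shape} vs model {p.data.shape}"
                )
            p.data = arr.copy()


class Linear(Module):
    """Affine map ``x @ W + b``; Glorot-uniform initialised."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, bias: bool = True):
        bound = np.sqrt(6.0 / (n_in + n_out))
        self.weight = Parameter(rng.uniform(-bound, bound, size=(n_in, n_out)))
        self.bias = Parameter(np.zeros(n_out)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class Embedding(Module):
    """Lookup table; row gather with scatter-add backward."""

    def __init__(self, n_rows: int, dim: int, rng: np.random.Generator, scale: float = 0.1):
        self.weight = Parameter(rng.normal(0.0, scale, size=(n_rows, dim)))

    def __call__(self, indices) -> Tensor:
        return self.weight.take(np.asarray(indices, dtype=np.intp), axis=0)


class LayerNorm(Module):
    """Layer normalisation over the last axis."""

    def __init__(self, dim: int, eps: float = 1e-5):
        self.gain = Parameter(np.ones(dim))
        self.shift = Parameter(np.zeros(dim))
        self._eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered**2).mean(axis=-1, keepdims=True)
        return centered / (var + self._eps) ** 0.5 * self.gain + self.shift


def sliding_windows(x: Tensor, kernel: int) -> Tensor:
    """im2col for a 1-D convolution.

    ``x`` has shape ``(L, C)``; returns ``(L - kernel + 1, kernel * C)`` where
    row ``i`` is the flattened window ``x[i : i + kernel]``.  The convolution
    itself is then a matmul with a ``(kernel * C, n_filters)`` weight.
    """
    length = x.shape[0]
    if length < kernel:
        raise ValueError(f"sequence of length {length} shorter than kernel {kernel}")
    cols = [x.take(np.arange(i, length - kernel + 1 + i), axis=0) for i in range(kernel)]
    return concat(cols, axis=1)
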