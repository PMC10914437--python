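"""Small neural-network building blocks on top of the autodiff engine."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, leaky_relu

__all__ = ["Module", "Linear", "Embedding", "MLP"]


class Module:
    """Base class: parameter discovery, flat state dict, (de)serialization."""

    def parameters(self) -> list[Tensor]:
        return [t for _, t in self.named_parameters()]

    def named_parameters(self, prefix: str = ""):
        out = []
        for name, value in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(value, Tensor) and value.requires_grad:
                out.append((key, value))
            elif isinstance(value, Module):
                out.extend(value.named_parameters(prefix=f"{key}."))
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        out.extend(item.named_parameters(prefix=f"{key}.{i}."))
                    elif isinstance(item, Tensor) and item.requires_grad:
                        out.append((f"{key}.{i}", item))
        return out

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        missing = set(params) ^ set(state)
        if missing:
            raise KeyError(f"state dict mismatch on keys: {sorted(missing)}")
        for k, v in state.items():
            arr = np.asarray(v, dtype=np.float64)
            if arr.shape != params[k].shape:
                raise ValueError(f"shape mismatch for {k}: {arr.shape} vs {params[k].shape}")
            params[k].data = arr.copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, gain: float = 1.0):
        scale = gain / np.sqrt(n_in)
        self.weight = Tensor(rng.normal(0.0, scale, size=(n_in, n_out)), requires_grad=True)
        self.bias = Tensor(np.zeros(n_out), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Embedding(Module):
    def __init__(self, n_items: int, dim: int, rng: np.random.Generator):
        self.weight = Tensor(rng.normal(0.0, 1.0 / np.sqrt(dim), size=(n_items, dim)), requires_grad=True)

    def forward(self, idx: np.ndarray) -> Tensor:
        return self.weight[np.asarray(idx, dtype=np.intp)]


class MLP(Module):
    """Leaky-ReLU MLP; no activation after the last layer."""

    def __init__(self, sizes: list[int], rng: np.random.Generator, slope: float = 0.2):
        self.layers = [Linear(a, b, rng) for a, b in zip(sizes[:-1], sizes[1:])]
        self.slope = slope

    def forward(self, x: Tensor) -> Tensor:
        for i, layer in enumerate(self.layers):
            x = layer(x)
            if i < len(self.layers) - 1:
                x = leaky_relu(x, self.slope)
        return x
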