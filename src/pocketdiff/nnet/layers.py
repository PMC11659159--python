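"""Parameterized building blocks (linear layers, MLPs) on top of the tensor engine."""

from __future__ import annotations

import numpy as np

from .tensor import Tensor

__all__ = ["Linear", "MLP", "Module"]


class Module:
    """Base class keeping an ordered parameter registry."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for v in vars(self).values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError(f"expected {len(params)} arrays, got {len(arrays)}")
        for p, a in zip(params, arrays):
            a = np.asarray(a, dtype=np.float64)
            if a.shape != p.data.shape:
                raise ValueError(f"shape mismatch {a.shape} vs {p.data.shape}")
            p.data = a.copy()


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(1.0 / n_in)
        self.weight = Tensor(rng.uniform(-scale, scale, (n_in, n_out)), requires_grad=True)
        self.bias = Tensor(np.zeros(n_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class MLP(Module):
    """Stack of linear layers with SiLU activations between (none after last)."""

    def __init__(self, widths, rng: np.random.Generator, final_activation: str | None = None):
        self.layers = [Linear(a, b, rng) for a, b in zip(widths[:-1], widths[1:])]
        self.final_activation = final_activation

    def __call__(self, x: Tensor) -> Tensor:
        for i, layer in enumerate(self.layers):
            x = layer(x)
            if i < len(self.layers) - 1:
                x = x.silu()
        if self.final_activation == "sigmoid":
            x = x.sigmoid()
        elif self.final_activation == "tanh":
            x = x.tanh()
        return x
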