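"""Parameterized layers and the Adam optimizer for the autodiff core."""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, get_default_dtype

__all__ = ["Module", "Linear", "MLP", "TransformerLayer", "Adam"]


class Module:
    """Base class: parameter registry with (de)serialization support."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Tensor) and item.requires_grad:
                        params.append(item)
        return params

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError(
                f"expected {len(params)} parameter arrays, got {len(arrays)}")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError(
                    f"shape mismatch: {p.data.shape} vs {a.shape}")
            p.data = np.array(a, dtype=get_default_dtype())

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()


class Linear(Module):
    """Affine map with He/Glorot-style scaled-normal initialization."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 scale: float | None = None):
        std = scale if scale is not None else np.sqrt(2.0 / d_in)
        self.weight = Tensor(rng.normal(0.0, std, size=(d_in, d_out)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(d_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        if x.ndim > 2:  # flatten leading axes: one big GEMM beats a loop
            lead = x.shape[:-1]
            out = x.reshape(-1, x.shape[-1]) @ self.weight + self.bias
            return out.reshape(*lead, out.shape[-1])
        return x @ self.weight + self.bias


class MLP(Module):
    """Fully connected stack with ReLU between layers (linear output)."""

    def __init__(self, dims: list[int], rng: np.random.Generator,
                 final_activation: bool = False):
        self.layers = [Linear(a, b, rng) for a, b in zip(dims, dims[1:])]
        self.final_activation = final_activation

    def __call__(self, x: Tensor) -> Tensor:
        for i, layer in enumerate(self.layers):
            x = layer(x)
            if i < len(self.layers) - 1 or self.final_activation:
                x = x.relu()
        return x


class TransformerLayer(Module):
    """Pre-activation style encoder layer: multi-head self-attention with a
    residual connection and layer norm, then a position-wise feed-forward
    block (expansion factor 2) with residual and layer norm."""

    def __init__(self, d_model: int, n_heads: int, rng: np.random.Generator):
        if d_model % n_heads:
            raise ValueError(
                f"n_heads={n_heads} must divide d_model={d_model}")
        self.d_model = d_model
        self.n_heads = n_heads
        self.d_head = d_model // n_heads
        s = np.sqrt(1.0 / d_model)
        self.wq = Linear(d_model, d_model, rng, scale=s)
        self.wk = Linear(d_model, d_model, rng, scale=s)
        self.wv = Linear(d_model, d_model, rng, scale=s)
        self.wo = Linear(d_model, d_model, rng, scale=s)
        self.ff1 = Linear(d_model, 2 * d_model, rng)
        self.ff2 = Linear(2 * d_model, d_model, rng)

    def _attend(self, x: Tensor) -> Tensor:
        # x: (batch, tokens, d_model)
        b, t, d = x.shape
        h, dh = self.n_heads, self.d_head

        def heads(z: Tensor) -> Tensor:
            return z.reshape(b, t, h, dh).transpose(0, 2, 1, 3)

        q, k, v = heads(self.wq(x)), heads(self.wk(x)), heads(self.wv(x))
        scores = (q @ k.swapaxes(-1, -2)) * (1.0 / np.sqrt(dh))
        attn = scores.softmax(axis=-1)
        ctx = (attn @ v).transpose(0, 2, 1, 3).reshape(b, t, d)
        return self.wo(ctx)

    def __call__(self, x: Tensor) -> Tensor:
        x = (x + self._attend(x)).layer_norm()
        x = (x + self.ff2(self.ff1(x).relu())).layer_norm()
        return x


class Adam:
    """Standard Adam with bias correction."""

    def __init__(self, params: list[Tensor], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            m *= self.b1
            m += (1.0 - self.b1) * p.grad
            v *= self.b2
            v += (1.0 - self.b2) * p.grad ** 2
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()
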