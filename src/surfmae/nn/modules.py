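"""Neural-network building blocks on top of the autograd tape.

Weight initialisation is explicit: every module takes a ``numpy.random.
Generator`` at construction so that a network built from a given seed is
bit-reproducible.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, concatenate


class Module:
    """Base class: tracks parameters and sub-modules via attribute assignment."""

    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_buffers", {})
        object.__setattr__(self, "_modules", {})

    def __setattr__(self, name, value):
        if isinstance(value, Tensor) and value.requires_grad:
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name, array: np.ndarray):
        """Non-trainable state saved with the model (e.g. fixed projections)."""
        self._buffers[name] = np.asarray(array, dtype=np.float64)
        object.__setattr__(self, name, self._buffers[name])

    def parameters(self) -> list[Tensor]:
        out = list(self._params.values())
        for m in self._modules.values():
            out.extend(m.parameters())
        return out

    def named_parameters(self, prefix: str = "") -> dict[str, Tensor]:
        out = {prefix + k: v for k, v in self._params.items()}
        for name, m in self._modules.items():
            out.update(m.named_parameters(prefix + name + "."))
        return out

    def modules(self) -> list["Module"]:
        out = [self]
        for m in self._modules.values():
            out.extend(m.modules())
        return out

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def named_buffers(self, prefix: str = "") -> dict[str, np.ndarray]:
        out = {prefix + k: v for k, v in self._buffers.items()}
        for name, m in self._modules.items():
            out.update(m.named_buffers(prefix + name + "."))
        return out

    def state_dict(self) -> dict[str, np.ndarray]:
        out = {k: v.data.copy() for k, v in self.named_parameters().items()}
        out.update({k: v.copy() for k, v in self.named_buffers().items()})
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]):
        params = self.named_parameters()
        own = set(params) | set(self.named_buffers())
        missing = own - set(state)
        extra = set(state) - own
        if missing or extra:
            raise KeyError(f"state dict mismatch: missing={sorted(missing)} extra={sorted(extra)}")
        for k, p in params.items():
            if p.data.shape != state[k].shape:
                raise ValueError(f"shape mismatch for {k}: {p.data.shape} vs {state[k].shape}")
            p.data = np.asarray(state[k], dtype=np.float64).copy()
        self._load_buffers(state, "")

    def _load_buffers(self, state: dict[str, np.ndarray], prefix: str):
        for k in list(self._buffers):
            self.register_buffer(k, state[prefix + k])
        for name, m in self._modules.items():
            m._load_buffers(state, prefix + name + ".")

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator, bias: bool = True):
        super().__init__()
        # Lecun-style fan-in scaling keeps pre-activations O(1) at any width
        scale = 1.0 / np.sqrt(d_in)
        self.weight = Tensor(rng.uniform(-scale, scale, size=(d_in, d_out)), requires_grad=True)
        self.bias = Tensor(np.zeros(d_out), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        y = x @ self.weight
        if self.bias is not None:
            y = y + self.bias
        return y


class MLP(Module):
    """Stack of Linear layers with a nonlinearity between (none after the last).

    ``act`` is "gelu" (default) or "relu"; ReLU is used on the wide per-point
    tensors where the smooth activation buys nothing but costs tanh calls.
    """

    def __init__(self, widths: list[int], rng: np.random.Generator, act: str = "gelu"):
        super().__init__()
        if act not in ("gelu", "relu"):
            raise ValueError(f"unknown activation {act!r}")
        self.act = act
        self.n_layers = len(widths) - 1
        for i in range(self.n_layers):
            setattr(self, f"lin{i}", Linear(widths[i], widths[i + 1], rng))

    def forward(self, x: Tensor) -> Tensor:
        for i in range(self.n_layers):
            x = getattr(self, f"lin{i}")(x)
            if i < self.n_layers - 1:
                x = x.gelu() if self.act == "gelu" else x.relu()
        return x


class LayerNorm(Module):
    def __init__(self, d: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones(d), requires_grad=True)
        self.beta = Tensor(np.zeros(d), requires_grad=True)
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        xn = xc / ((var + self.eps) ** 0.5)
        return xn * self.gamma + self.beta


class MultiheadSelfAttention(Module):
    def __init__(self, d: int, n_heads: int, rng: np.random.Generator):
        super().__init__()
        if d % n_heads != 0:
            raise ValueError(f"width {d} not divisible by {n_heads} heads")
        self.d, self.n_heads, self.d_head = d, n_heads, d // n_heads
        self.qkv = Linear(d, 3 * d, rng)
        self.proj = Linear(d, d, rng)

    def forward(self, x: Tensor) -> Tensor:
        q_len = x.shape[0]
        qkv = self.qkv(x).reshape(q_len, 3, self.n_heads, self.d_head)
        qkv = qkv.transpose(1, 2, 0, 3)  # (3, heads, q, d_head)
        q, k, v = qkv[0], qkv[1], qkv[2]
        att = (q @ k.transpose(0, 2, 1)) * (1.0 / np.sqrt(self.d_head))
        att = att.softmax(axis=-1)
        out = (att @ v).transpose(1, 0, 2).reshape(q_len, self.d)
        return self.proj(out)


class TransformerBlock(Module):
    """Pre-norm block: x + Att(LN(x)); x + MLP(LN(x))."""

    def __init__(self, d: int, n_heads: int, mlp_ratio: int, rng: np.random.Generator):
        super().__init__()
        self.norm1 = LayerNorm(d)
        self.attn = MultiheadSelfAttention(d, n_heads, rng)
        self.norm2 = LayerNorm(d)
        self.mlp = MLP([d, mlp_ratio * d, d], rng)

    def forward(self, x: Tensor) -> Tensor:
        x = x + self.attn(self.norm1(x))
        x = x + self.mlp(self.norm2(x))
        return x


class TransformerStack(Module):
    def __init__(self, d: int, depth: int, n_heads: int, mlp_ratio: int, rng: np.random.Generator):
        super().__init__()
        self.depth = depth
        for i in range(depth):
            setattr(self, f"block{i}", TransformerBlock(d, n_heads, mlp_ratio, rng))
        self.norm = LayerNorm(d)

    def forward(self, x: Tensor) -> Tensor:
        for i in range(self.depth):
            x = getattr(self, f"block{i}")(x)
        return self.norm(x)

    @property
    def blocks(self) -> list[TransformerBlock]:
        return [getattr(self, f"block{i}") for i in range(self.depth)]
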