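"""Neural building blocks on top of the autograd tape.

Modules register parameters under dotted names so model state can be
snapshotted (continual-learning checkpoints) and reloaded against the label
vocabulary that was active when the snapshot was taken.
"""

from __future__ import annotations

import math

import numpy as np

from .autograd import Tensor, concat, gather_rows

__all__ = [
    "Module", "Linear", "Embedding", "LayerNorm", "SelfAttentionLayer",
    "FeedForward", "AdamW", "sinusoidal_positions",
]


class Module:
    """Lightweight parameter container with recursive (name, Tensor) listing."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._modules: dict[str, "Module"] = {}

    def __setattr__(self, key, value):
        if isinstance(value, Tensor) and value.requires_grad:
            self.__dict__.setdefault("_params", {})[key] = value
        elif isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[key] = value
        object.__setattr__(self, key, value)

    def register(self, name: str, module: "Module") -> "Module":
        self._modules[name] = module
        object.__setattr__(self, name.replace(".", "_"), module)
        return module

    def named_parameters(self, prefix: str = ""):
        for name, p in self._params.items():
            yield (prefix + name, p)
        for name, m in self._modules.items():
            yield from m.named_parameters(prefix + name + ".")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray], strict: bool = True) -> None:
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        if missing and strict:
            raise KeyError(f"state dict missing parameters: {sorted(missing)}")
        for name, p in own.items():
            if name not in state:
                continue
            if p.data.shape != state[name].shape:
                raise ValueError(
                    f"shape mismatch for {name}: {p.data.shape} vs {state[name].shape}")
            p.data = state[name].copy()


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = math.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        super().__init__()
        self.weight = Tensor(_glorot(rng, in_dim, out_dim), requires_grad=True)
        self.bias = Tensor(np.zeros(out_dim), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Embedding(Module):
    def __init__(self, n_rows: int, dim: int, rng: np.random.Generator, scale: float = 0.1):
        super().__init__()
        self.weight = Tensor(rng.normal(0.0, scale, size=(n_rows, dim)), requires_grad=True)

    def __call__(self, indices: np.ndarray) -> Tensor:
        return gather_rows(self.weight, indices)


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.gain = Tensor(np.ones(dim), requires_grad=True)
        self.shift = Tensor(np.zeros(dim), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centred = x - mu
        var = (centred * centred).mean(axis=-1, keepdims=True)
        return centred / (var + self.eps).sqrt() * self.gain + self.shift


class SelfAttentionLayer(Module):
    """One pre-norm transformer block: multi-head self-attention + FFN."""

    def __init__(self, dim: int, n_heads: int, ffn_dim: int, rng: np.random.Generator):
        super().__init__()
        if dim % n_heads != 0:
            raise ValueError("dim must be divisible by n_heads")
        self.dim, self.n_heads, self.head_dim = dim, n_heads, dim // n_heads
        self.wq = Linear(dim, dim, rng)
        self.wk = Linear(dim, dim, rng)
        self.wv = Linear(dim, dim, rng)
        self.wo = Linear(dim, dim, rng)
        self.ln1 = LayerNorm(dim)
        self.ln2 = LayerNorm(dim)
        self.ff1 = Linear(dim, ffn_dim, rng)
        self.ff2 = Linear(ffn_dim, dim, rng)

    def _attend(self, x: Tensor) -> Tensor:
        n = x.shape[0]
        q = self.wq(x).reshape(n, self.n_heads, self.head_dim).transpose(0, 1)
        k = self.wk(x).reshape(n, self.n_heads, self.head_dim).transpose(0, 1)
        v = self.wv(x).reshape(n, self.n_heads, self.head_dim).transpose(0, 1)
        scores = (q @ k.transpose(-2, -1)) * (1.0 / math.sqrt(self.head_dim))
        attn = scores.softmax(axis=-1)
        ctx = (attn @ v).transpose(0, 1).reshape(n, self.dim)
        return self.wo(ctx)

    def __call__(self, x: Tensor) -> Tensor:
        x = x + self._attend(self.ln1(x))
        h = self.ff2(self.ff1(self.ln2(x)).relu())
        return x + h


class FeedForward(Module):
    """Two affine layers with a nonlinearity between (the classifier head shape)."""

    def __init__(self, in_dim: int, hidden_dim: int, out_dim: int, rng: np.random.Generator):
        super().__init__()
        self.fc1 = Linear(in_dim, hidden_dim, rng)
        self.fc2 = Linear(hidden_dim, out_dim, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).tanh())


def sinusoidal_positions(n: int, dim: int) -> np.ndarray:
    """Fixed sinusoidal position encodings, shape (n, dim)."""
    pos = np.arange(n)[:, None].astype(np.float64)
    i = np.arange(dim // 2)[None, :].astype(np.float64)
    angles = pos / np.power(10000.0, 2.0 * i / dim)
    enc = np.zeros((n, dim))
    enc[:, 0::2] = np.sin(angles)
    enc[:, 1::2] = np.cos(angles)
    return enc


class AdamW:
    """Decoupled-weight-decay Adam. Parameters may be added between steps

    (head expansion, marker-embedding growth): state is keyed by tensor
    identity and created lazily, so existing moments are untouched.
    """

    def __init__(self, lr: float = 5e-4, betas=(0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.01):
        self.lr, self.betas, self.eps, self.weight_decay = lr, betas, eps, weight_decay
        self._state: dict[int, dict] = {}

    def step(self, params: list[Tensor]) -> None:
        b1, b2 = self.betas
        for p in params:
            if p.grad is None:
                continue
            st = self._state.setdefault(id(p), {
                "t": 0, "m": np.zeros_like(p.data), "v": np.zeros_like(p.data)})
            st["t"] += 1
            st["m"] = b1 * st["m"] + (1 - b1) * p.grad
            st["v"] = b2 * st["v"] + (1 - b2) * p.grad ** 2
            m_hat = st["m"] / (1 - b1 ** st["t"])
            v_hat = st["v"] / (1 - b2 ** st["t"])
            p.data -= self.lr * (m_hat / (np.sqrt(v_hat) + self.eps)
                                 + self.weight_decay * p.data)
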