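"""Transformer building blocks on the numpy autograd engine.

Pre-norm ViT-style blocks, factorized 3D sinusoidal position codes and the
block-diagonal attention mask implementing the variable-length packing
contract (tokens of different samples never attend to each other).
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor

__all__ = ["Module", "Linear", "LayerNorm", "MultiheadSelfAttention",
           "TransformerBlock", "TransformerEncoder", "sincos3d", "block_mask"]

_NEG = -1e30


class Module:
    """Lightweight container with recursive, deterministic parameter walk."""

    def named_params(self, prefix: str = "") -> dict[str, Tensor]:
        out: dict[str, Tensor] = {}
        for name, val in self.__dict__.items():
            key = f"{prefix}{name}"
            if isinstance(val, Tensor):
                out[key] = val
            elif isinstance(val, Module):
                out.update(val.named_params(f"{key}."))
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        out.update(item.named_params(f"{key}.{i}."))
        return out

    def params(self) -> list[Tensor]:
        return list(self.named_params().values())

    def zero_grad(self):
        for p in self.params():
            p.grad = None

    def state_arrays(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.named_params().items()}

    def load_state_arrays(self, state: dict[str, np.ndarray]):
        named = self.named_params()
        if set(named) != set(state):
            raise ValueError("parameter name mismatch while loading state")
        for k, p in named.items():
            if p.data.shape != state[k].shape:
                raise ValueError(f"shape mismatch for {k}")
            p.data = np.asarray(state[k], dtype=np.float64).copy()


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 bias: bool = True):
        self.weight = Tensor(rng.normal(0.0, 0.02, size=(d_in, d_out)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(d_out), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        return out + self.bias if self.bias is not None else out


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-6):
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self._eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        m = x.mean(axis=-1, keepdims=True)
        d = x - m
        v = (d * d).mean(axis=-1, keepdims=True)
        return d * (v + self._eps) ** -0.5 * self.gamma + self.beta


class MultiheadSelfAttention(Module):
    def __init__(self, dim: int, heads: int, rng: np.random.Generator):
        if dim % heads:
            raise ValueError("dim must be divisible by heads")
        self.heads = heads
        self.qkv = Linear(dim, 3 * dim, rng)
        self.proj = Linear(dim, dim, rng)

    def __call__(self, x: Tensor, mask: np.ndarray | None = None) -> Tensor:
        n, d = x.shape
        h, dh = self.heads, d // self.heads
        qkv = self.qkv(x).reshape(n, 3, h, dh).transpose(1, 2, 0, 3)
        q, k, v = qkv[0], qkv[1], qkv[2]  # each (h, n, dh)
        scores = (q @ k.transpose(0, 2, 1)) * (dh ** -0.5)
        if mask is not None:
            scores = scores + Tensor(mask)
        attn = scores.softmax(axis=-1)
        out = (attn @ v).transpose(1, 0, 2).reshape(n, d)
        return self.proj(out)


class TransformerBlock(Module):
    """Pre-norm block: x + MHA(LN(x)); x + MLP(LN(x)) with GELU."""

    def __init__(self, dim: int, heads: int, rng: np.random.Generator,
                 mlp_ratio: float = 4.0):
        self.norm1 = LayerNorm(dim)
        self.attn = MultiheadSelfAttention(dim, heads, rng)
        self.norm2 = LayerNorm(dim)
        hidden = int(dim * mlp_ratio)
        self.fc1 = Linear(dim, hidden, rng)
        self.fc2 = Linear(hidden, dim, rng)

    def __call__(self, x: Tensor, mask: np.ndarray | None = None) -> Tensor:
        x = x + self.attn(self.norm1(x), mask)
        return x + self.fc2(self.fc1(self.norm2(x)).gelu())


class TransformerEncoder(Module):
    """Stack of pre-norm blocks over a flat packed token sequence."""

    def __init__(self, d_in: int, dim: int, depth: int, heads: int,
                 rng: np.random.Generator):
        self.embed = Linear(d_in, dim, rng)
        self.blocks = [TransformerBlock(dim, heads, rng) for _ in range(depth)]
        self.norm = LayerNorm(dim)
        self.dim = dim

    def __call__(self, values: np.ndarray, pos: np.ndarray,
                 lengths: np.ndarray | None = None) -> Tensor:
        x = self.embed(Tensor(values)) + Tensor(pos)
        mask = block_mask(lengths) if lengths is not None else None
        for blk in self.blocks:
            x = blk(x, mask)
        return self.norm(x)


def block_mask(lengths: np.ndarray) -> np.ndarray | None:
    """Additive attention mask that confines attention within each sample's
    span of the packed sequence."""
    lengths = np.asarray(lengths)
    if len(lengths) == 1:
        return None
    n = int(lengths.sum())
    owner = np.repeat(np.arange(len(lengths)), lengths)
    mask = np.where(owner[:, None] == owner[None, :], 0.0, _NEG)
    assert mask.shape == (n, n)
    return mask


def sincos3d(coords: np.ndarray, dim: int) -> np.ndarray:
    """Factorized 3D sin/cos position code: the embedding is split into
    three per-axis chunks, each a standard 1D sinusoid of the patch index."""
    if dim % 2:
        raise ValueError("position dim must be even")
    coords = np.asarray(coords, dtype=np.float64)
    base = (dim // 2) // 3 * 2
    chunks = [base, base, base]
    rem = (dim - 3 * base) // 2
    for i in range(rem):
        chunks[i] += 2
    parts = []
    for ax, c in enumerate(chunks):
        half = c // 2
        freqs = 1.0 / (10000.0 ** (np.arange(half) / max(half, 1)))
        ang = coords[:, ax:ax + 1] * freqs[None, :]
        parts.append(np.sin(ang))
        parts.append(np.cos(ang))
    return np.concatenate(parts, axis=1)
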