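"""Neural layers built on the autodiff engine.

Conventions: batch-first tensors (B, T, d); key-padding masks are boolean
numpy arrays with True = observed.  Masked attention uses an exact fill of
-inf on the logits, so masked keys receive weight exactly 0.0 and the output
is bitwise independent of their values.
"""
from __future__ import annotations

import numpy as np

from .autodiff import Tensor, concat


class Module:
    """Tiny module base: tracks Parameters of itself and sub-modules."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        seen: set[int] = set()
        stack: list[object] = [self]
        while stack:
            obj = stack.pop()
            if id(obj) in seen:
                continue
            seen.add(id(obj))
            for value in vars(obj).values():
                if isinstance(value, Tensor) and value.requires_grad:
                    if id(value) not in seen:
                        seen.add(id(value))
                        params.append(value)
                elif isinstance(value, Module):
                    stack.append(value)
                elif isinstance(value, (list, tuple)):
                    stack.extend(v for v in value if isinstance(v, (Module, Tensor)))
        return params

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        self._collect_state("", out)
        return out

    def _collect_state(self, prefix: str, out: dict[str, np.ndarray]) -> None:
        # all Tensor attributes are parameters (there are no buffers), so
        # frozen (requires_grad=False) weights are included too
        for name, value in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(value, Tensor):
                out[key] = value.data.copy()
            elif isinstance(value, Module):
                value._collect_state(key + ".", out)
            elif isinstance(value, (list, tuple)):
                for i, v in enumerate(value):
                    if isinstance(v, Module):
                        v._collect_state(f"{key}.{i}.", out)
                    elif isinstance(v, Tensor):
                        out[f"{key}.{i}"] = v.data.copy()

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = {}
        self._collect_refs("", own)
        missing = set(state) ^ set(own)
        if missing:
            raise KeyError(f"state dict mismatch on keys: {sorted(missing)}")
        for key, tensor in own.items():
            arr = np.asarray(state[key], dtype=np.float64)
            if arr.shape != tensor.data.shape:
                raise ValueError(f"shape mismatch for {key}")
            tensor.data = arr.copy()

    def _collect_refs(self, prefix: str, out: dict[str, Tensor]) -> None:
        for name, value in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(value, Tensor):
                out[key] = value
            elif isinstance(value, Module):
                value._collect_refs(key + ".", out)
            elif isinstance(value, (list, tuple)):
                for i, v in enumerate(value):
                    if isinstance(v, Module):
                        v._collect_refs(f"{key}.{i}.", out)
                    elif isinstance(v, Tensor):
                        out[f"{key}.{i}"] = v


def parameter(rng: np.random.Generator, shape, scale: float | None = None) -> Tensor:
    if scale is None:
        fan_in = shape[0] if len(shape) > 1 else max(shape[0], 1)
        scale = 1.0 / np.sqrt(fan_in)
    t = Tensor(rng.normal(0.0, scale, size=shape), requires_grad=True)
    return t


class Linear(Module):
    def __init__(self, rng, in_dim: int, out_dim: int, zero_init: bool = False):
        if zero_init:
            self.weight = Tensor(np.zeros((in_dim, out_dim)), requires_grad=True)
        else:
            self.weight = parameter(rng, (in_dim, out_dim))
        self.bias = Tensor(np.zeros(out_dim), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=-1, keepdims=True)
        return centered / (var + self.eps).sqrt() * self.gamma + self.beta


class FeedForward(Module):
    def __init__(self, rng, dim: int, hidden: int):
        self.fc1 = Linear(rng, dim, hidden)
        self.fc2 = Linear(rng, hidden, dim)

    def __call__(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).relu())


class MultiHeadAttention(Module):
    """Multi-head attention with an optional key-padding mask.

    ``key_mask`` has shape (B, T_kv), True = attend.  Masked keys get -inf
    logits, hence softmax weight exactly 0.
    """

    def __init__(self, rng, dim: int, n_heads: int):
        if dim % n_heads:
            raise ValueError(f"embed_dim {dim} not divisible by n_heads {n_heads}")
        self.dim, self.n_heads, self.head_dim = dim, n_heads, dim // n_heads
        self.wq = Linear(rng, dim, dim)
        self.wk = Linear(rng, dim, dim)
        self.wv = Linear(rng, dim, dim)
        self.wo = Linear(rng, dim, dim)

    def __call__(
        self,
        query: Tensor,
        key: Tensor,
        value: Tensor,
        key_mask: np.ndarray | None = None,
        return_weights: bool = False,
    ):
        B, Tq, _ = query.shape
        Tk = key.shape[1]
        h, dh = self.n_heads, self.head_dim

        def split(x: Tensor, T: int) -> Tensor:
            return x.reshape(B, T, h, dh).transpose(0, 2, 1, 3)  # (B,h,T,dh)

        q = split(self.wq(query), Tq)
        k = split(self.wk(key), Tk)
        v = split(self.wv(value), Tk)
        logits = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(dh))  # (B,h,Tq,Tk)
        if key_mask is not None:
            mask = np.asarray(key_mask, bool)[:, None, None, :]
            if not mask.any(axis=-1).all():
                raise ValueError("no observed modality: all attention keys masked")
            logits = logits.masked_fill(np.broadcast_to(mask, logits.shape), -np.inf)
        weights = logits.softmax(axis=-1)
        out = weights @ v  # (B,h,Tq,dh)
        out = out.transpose(0, 2, 1, 3).reshape(B, Tq, self.dim)
        out = self.wo(out)
        if return_weights:
            return out, weights.data.copy()
        return out


class TransformerEncoderLayer(Module):
    """Pre-norm self-attention block."""

    def __init__(self, rng, dim: int, n_heads: int, ff_hidden: int):
        self.norm1 = LayerNorm(dim)
        self.attn = MultiHeadAttention(rng, dim, n_heads)
        self.norm2 = LayerNorm(dim)
        self.ff = FeedForward(rng, dim, ff_hidden)

    def __call__(self, x: Tensor, key_mask: np.ndarray | None = None) -> Tensor:
        h = self.norm1(x)
        x = x + self.attn(h, h, h, key_mask=key_mask)
        return x + self.ff(self.norm2(x))


class CrossAttentionLayer(Module):
    """Pre-norm masked cross-attention + feed-forward block for the fusion
    module: queries attend over a (masked) token bank."""

    def __init__(self, rng, dim: int, n_heads: int, ff_hidden: int):
        self.norm_q = LayerNorm(dim)
        self.norm_kv = LayerNorm(dim)
        self.attn = MultiHeadAttention(rng, dim, n_heads)
        self.norm2 = LayerNorm(dim)
        self.ff = FeedForward(rng, dim, ff_hidden)

    def __call__(self, q: Tensor, tokens: Tensor, key_mask: np.ndarray):
        kv = self.norm_kv(tokens)
        attended, weights = self.attn(
            self.norm_q(q), kv, kv, key_mask=key_mask, return_weights=True
        )
        q = q + attended
        q = q + self.ff(self.norm2(q))
        return q, weights


class Adaptor(Module):
    """Two-layer modality-specific adaptor with a residual connection."""

    def __init__(self, rng, dim: int, hidden: int):
        self.fc1 = Linear(rng, dim, hidden)
        self.fc2 = Linear(rng, hidden, dim)
        self.norm = LayerNorm(dim)

    def __call__(self, x: Tensor) -> Tensor:
        return x + self.fc2(self.fc1(self.norm(x)).relu())


class Adam:
    def __init__(self, params: list[Tensor], lr: float = 1e-4,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            self.m[i] = b1 * self.m[i] + (1 - b1) * p.grad
            self.v[i] = b2 * self.v[i] + (1 - b2) * p.grad**2
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()


def softclip(x: Tensor, lo: float, hi: float, beta: float = 20.0) -> Tensor:
    """Smooth clamp to (lo, hi): identity (to float64 precision) in the
    interior, saturating at the bounds.  sc(x) = lo + sp(x-lo) - sp(x-hi)."""
    return lo + (x - lo).softplus(beta) - (x - hi).softplus(beta)
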