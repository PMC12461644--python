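"""Neural-network layers on the autodiff tape."""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, concatenate
from . import functional as F

__all__ = [
    "Module", "ModuleList", "Linear", "LayerNorm", "Embedding",
    "Conv2d", "DepthwiseConv2d", "HyperConv2d", "HyperDepthwiseConv2d",
    "MultiHeadSelfAttention", "TransformerBlock", "AttentionPool2d",
    "SelfAttention2d",
]


def _param(rng: np.random.Generator, shape, scale: float) -> Tensor:
    return Tensor(rng.normal(0.0, scale, size=shape).astype(np.float32), requires_grad=True)


class Module:
    """Container base class: parameter discovery, mode switching, state dicts."""

    def __init__(self):
        self._training = True

    # attribute walking ------------------------------------------------
    def named_parameters(self, prefix: str = ""):
        for name, val in vars(self).items():
            if name.startswith("_"):
                continue
            key = f"{prefix}{name}"
            if isinstance(val, Tensor):
                yield key, val
            elif isinstance(val, Module):
                yield from val.named_parameters(f"{key}.")
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{key}.{i}.")
                    elif isinstance(item, Tensor):
                        yield f"{key}.{i}", item

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def train(self, mode: bool = True):
        self._training = mode
        for val in vars(self).values():
            if isinstance(val, Module):
                val.train(mode)
            elif isinstance(val, (list, tuple)):
                for item in val:
                    if isinstance(item, Module):
                        item.train(mode)
        return self

    def eval(self):
        return self.train(False)

    @property
    def training(self) -> bool:
        return self._training

    def n_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    # state ------------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: p.data.copy() for k, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]):
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        if missing:
            raise KeyError(f"missing parameters in state dict: {sorted(missing)[:5]}")
        for k, p in own.items():
            arr = np.asarray(state[k])
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {k}: {arr.shape} vs {p.data.shape}")
            p.data = arr.astype(p.data.dtype).copy()
        return self

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class ModuleList(Module):
    def __init__(self, mods):
        super().__init__()
        self.items = list(mods)

    def __iter__(self):
        return iter(self.items)

    def __len__(self):
        return len(self.items)

    def __getitem__(self, i):
        return self.items[i]


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator, bias: bool = True):
        super().__init__()
        self.d_in, self.d_out = d_in, d_out
        self.weight = _param(rng, (d_in, d_out), d_in**-0.5)
        self.bias = Tensor(np.zeros(d_out, dtype=np.float32), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        y = x @ self.weight
        if self.bias is not None:
            y = y + self.bias
        return y


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.dim = dim
        self.eps = eps
        self.gamma = Tensor(np.ones(dim, dtype=np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(dim, dtype=np.float32), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return xc / (var + self.eps).sqrt() * self.gamma + self.beta


class Embedding(Module):
    def __init__(self, n: int, dim: int, rng: np.random.Generator):
        super().__init__()
        self.n, self.dim = n, dim
        self.weight = _param(rng, (n, dim), 0.02)

    def forward(self, idx: np.ndarray) -> Tensor:
        return self.weight[np.asarray(idx)]


class Conv2d(Module):
    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator,
                 stride: int = 1, padding: int | None = None, bias: bool = True):
        super().__init__()
        self.c_in, self.c_out, self.kernel = c_in, c_out, kernel
        self.stride = stride
        self.padding = kernel // 2 if padding is None else padding
        self.weight = _param(rng, (c_out, c_in, kernel, kernel), (c_in * kernel * kernel) ** -0.5)
        self.bias = Tensor(np.zeros(c_out, dtype=np.float32), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return F.conv2d(x, self.weight, self.bias, stride=self.stride, padding=self.padding)


class DepthwiseConv2d(Module):
    def __init__(self, channels: int, kernel: int, rng: np.random.Generator,
                 stride: int = 1, padding: int | None = None):
        super().__init__()
        self.channels, self.kernel = channels, kernel
        self.stride = stride
        self.padding = kernel // 2 if padding is None else padding
        self.weight = _param(rng, (channels, kernel, kernel), (kernel * kernel) ** -0.5)
        self.bias = Tensor(np.zeros(channels, dtype=np.float32), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return F.depthwise_conv2d(x, self.weight, self.bias,
                                  stride=self.stride, padding=self.padding)


class HyperConv2d(Module):
    """Convolution whose kernels are generated from a conditioning vector.

    The kernel bank for sample ``b`` is ``W0 + sum_r c_r(T_b) * B_r`` where the
    coefficients ``c(T)`` come from a two-layer perceptron and ``B_r`` is a
    small learned basis (grouped low-rank factorization of the full
    hyper-network output).  Zeroing the perceptron makes the layer an ordinary
    convolution, independent of the conditioning vector.
    """

    def __init__(self, c_in: int, c_out: int, kernel: int, cond_dim: int,
                 rng: np.random.Generator, stride: int = 1, padding: int | None = None,
                 rank: int = 8, hidden: int = 64):
        super().__init__()
        self.c_in, self.c_out, self.kernel = c_in, c_out, kernel
        self.cond_dim, self.rank = cond_dim, rank
        self.stride = stride
        self.padding = kernel // 2 if padding is None else padding
        fan = (c_in * kernel * kernel) ** -0.5
        self.base_weight = _param(rng, (c_out, c_in, kernel, kernel), fan)
        self.base_bias = Tensor(np.zeros(c_out, dtype=np.float32), requires_grad=True)
        self.basis = _param(rng, (rank, c_out, c_in, kernel, kernel), fan)
        self.bias_basis = _param(rng, (rank, c_out), 0.01)
        # hyper-MLP: cond -> hidden -> rank coefficients (small init: start
        # close to the unconditional base convolution)
        self.hyper_in = Linear(cond_dim, hidden, rng)
        self.hyper_out = Linear(hidden, rank, rng)
        self.hyper_out.weight.data *= 0.1

    def coefficients(self, cond: Tensor) -> Tensor:
        return self.hyper_out(self.hyper_in(cond).gelu())

    def forward(self, x: Tensor, cond: Tensor) -> Tensor:
        """x: (B,C,H,W); cond: (B,cond_dim)."""
        c = self.coefficients(cond)                      # (B, R)
        B = x.shape[0]
        flat_basis = self.basis.reshape(self.rank, -1)   # (R, OCkk)
        w = (c @ flat_basis).reshape(B, self.c_out, self.c_in, self.kernel, self.kernel)
        w = w + self.base_weight.reshape(1, self.c_out, self.c_in, self.kernel, self.kernel)
        b = c @ self.bias_basis + self.base_bias
        return F.conv2d_batched(x, w, b, stride=self.stride, padding=self.padding)


class HyperDepthwiseConv2d(Module):
    """Depthwise convolution with per-sample kernels generated from a vector."""

    def __init__(self, channels: int, kernel: int, cond_dim: int,
                 rng: np.random.Generator, stride: int = 1, padding: int | None = None,
                 rank: int = 8, hidden: int = 64):
        super().__init__()
        self.channels, self.kernel = channels, kernel
        self.cond_dim, self.rank = cond_dim, rank
        self.stride = stride
        self.padding = kernel // 2 if padding is None else padding
        fan = (kernel * kernel) ** -0.5
        self.base_weight = _param(rng, (channels, kernel, kernel), fan)
        self.base_bias = Tensor(np.zeros(channels, dtype=np.float32), requires_grad=True)
        self.basis = _param(rng, (rank, channels, kernel, kernel), fan)
        self.bias_basis = _param(rng, (rank, channels), 0.01)
        self.hyper_in = Linear(cond_dim, hidden, rng)
        self.hyper_out = Linear(hidden, rank, rng)
        self.hyper_out.weight.data *= 0.1

    def forward(self, x: Tensor, cond: Tensor) -> Tensor:
        c = self.hyper_out(self.hyper_in(cond).gelu())  # (B, R)
        B = x.shape[0]
        w = (c @ self.basis.reshape(self.rank, -1)).reshape(
            B, self.channels, self.kernel, self.kernel)
        w = w + self.base_weight.reshape(1, self.channels, self.kernel, self.kernel)
        b = c @ self.bias_basis + self.base_bias
        return F.depthwise_conv2d_batched(x, w, b, stride=self.stride, padding=self.padding)


def _attend(q: Tensor, k: Tensor, v: Tensor, heads: int, mask: np.ndarray | None = None) -> Tensor:
    """q: (B,Lq,D), k/v: (B,Lk,D) -> (B,Lq,D) multi-head attention."""
    B, Lq, D = q.shape
    Lk = k.shape[1]
    hd = D // heads
    qh = q.reshape(B, Lq, heads, hd).transpose(0, 2, 1, 3)
    kh = k.reshape(B, Lk, heads, hd).transpose(0, 2, 1, 3)
    vh = v.reshape(B, Lk, heads, hd).transpose(0, 2, 1, 3)
    att = (qh @ kh.transpose(0, 1, 3, 2)) * (hd**-0.5)
    if mask is not None:
        att = att + Tensor(mask)
    att = att.softmax(axis=-1)
    out = (att @ vh).transpose(0, 2, 1, 3).reshape(B, Lq, D)
    return out


class MultiHeadSelfAttention(Module):
    def __init__(self, dim: int, heads: int, rng: np.random.Generator, causal: bool = False):
        super().__init__()
        if dim % heads:
            raise ValueError("dim must be divisible by heads")
        self.dim, self.heads, self.causal = dim, heads, causal
        self.qkv = Linear(dim, 3 * dim, rng)
        self.proj = Linear(dim, dim, rng)

    def forward(self, x: Tensor) -> Tensor:
        B, L, D = x.shape
        qkv = self.qkv(x)
        q, k, v = qkv[:, :, :D], qkv[:, :, D:2 * D], qkv[:, :, 2 * D:]
        mask = None
        if self.causal:
            mask = np.triu(np.full((L, L), -1e9, dtype=np.float32), k=1)
        return self.proj(_attend(q, k, v, self.heads, mask))


class TransformerBlock(Module):
    """Pre-norm transformer block (attention + 4x MLP)."""

    def __init__(self, dim: int, heads: int, rng: np.random.Generator, causal: bool = False):
        super().__init__()
        self.ln1 = LayerNorm(dim)
        self.attn = MultiHeadSelfAttention(dim, heads, rng, causal=causal)
        self.ln2 = LayerNorm(dim)
        self.fc1 = Linear(dim, 4 * dim, rng)
        self.fc2 = Linear(4 * dim, dim, rng)

    def forward(self, x: Tensor) -> Tensor:
        x = x + self.attn(self.ln1(x))
        x = x + self.fc2(self.fc1(self.ln2(x)).gelu())
        return x


class SelfAttention2d(Module):
    """Single-head pre-norm self-attention over a flattened feature grid."""

    def __init__(self, channels: int, rng: np.random.Generator):
        super().__init__()
        self.channels = channels
        self.norm = LayerNorm(channels)
        self.qkv = Linear(channels, 3 * channels, rng)
        self.proj = Linear(channels, channels, rng)
        self.proj.weight.data *= 0.1  # near-identity start

    def forward(self, x: Tensor) -> Tensor:
        B, C, H, W = x.shape
        tokens = x.reshape(B, C, H * W).transpose(0, 2, 1)
        t = self.norm(tokens)
        qkv = self.qkv(t)
        q, k, v = qkv[:, :, :C], qkv[:, :, C:2 * C], qkv[:, :, 2 * C:]
        out = self.proj(_attend(q, k, v, heads=1))
        return x + out.transpose(0, 2, 1).reshape(B, C, H, W)


class AttentionPool2d(Module):
    """Single QKV attention layer pooling a feature grid to one vector.

    The query is conditioned on the global average-pooled feature map; keys and
    values are the spatial positions.
    """

    def __init__(self, dim: int, heads: int, rng: np.random.Generator):
        super().__init__()
        self.dim, self.heads = dim, heads
        self.q = Linear(dim, dim, rng)
        self.k = Linear(dim, dim, rng)
        self.v = Linear(dim, dim, rng)
        self.proj = Linear(dim, dim, rng)

    def forward(self, x: Tensor) -> Tensor:
        """x: (B,C,H,W) -> (B,C)."""
        B, C, H, W = x.shape
        tokens = x.reshape(B, C, H * W).transpose(0, 2, 1)  # (B,L,C)
        query = tokens.mean(axis=1, keepdims=True)          # (B,1,C)
        out = _attend(self.q(query), self.k(tokens), self.v(tokens), self.heads)
        return self.proj(out).reshape(B, C)
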