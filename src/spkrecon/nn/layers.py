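"""Layers for 1D windowed-attention reconstruction networks.

Token layout is (batch, time, channels); every time sample is one token.
Attention is computed inside non-overlapping windows of `window` tokens, with
a learned relative position bias and, on shifted layers, a cyclic roll of
half a window plus an additive mask that blocks attention across the seam.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor

NEG_INF = -1e9


def trunc_normal(rng: np.random.Generator, shape, std: float = 0.02) -> np.ndarray:
    """Truncated normal at ±2 std, by resampling."""
    x = rng.normal(0.0, std, size=shape)
    bad = np.abs(x) > 2 * std
    while bad.any():
        x[bad] = rng.normal(0.0, std, size=int(bad.sum()))
        bad = np.abs(x) > 2 * std
    return x


def fan_in_uniform(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    bound = 1.0 / np.sqrt(fan_in)
    return rng.uniform(-bound, bound, size=shape)


class Module:
    """Base class: parameter collection and (de)serialization by name."""

    def parameters(self) -> list[Tensor]:
        params = []
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

    def named_parameters(self, prefix: str = "") -> list[tuple[str, Tensor]]:
        out = []
        for k, v in self.__dict__.items():
            name = f"{prefix}{k}"
            if isinstance(v, Tensor) and v.requires_grad:
                out.append((name, v))
            elif isinstance(v, Module):
                out.extend(v.named_parameters(f"{name}."))
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        out.extend(item.named_parameters(f"{name}.{i}."))
                    elif isinstance(item, Tensor) and item.requires_grad:
                        out.append((f"{name}.{i}", item))
        return out

    def n_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        extra = set(state) - set(own)
        if missing or extra:
            raise KeyError(f"state mismatch: missing={sorted(missing)}, extra={sorted(extra)}")
        for k, v in own.items():
            arr = np.asarray(state[k], dtype=np.float64)
            if arr.shape != v.data.shape:
                raise ValueError(f"shape mismatch for {k}: {arr.shape} vs {v.data.shape}")
            v.data = arr.copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        self.weight = Tensor(trunc_normal(rng, (d_in, d_out)), requires_grad=True)
        self.bias = Tensor(np.zeros(d_out), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Conv1d(Module):
    """kernel (k, c_in, c_out); 'same' zero padding unless causal."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator,
                 padding: str = "same", dilation: int = 1):
        fan_in = c_in * kernel
        self.weight = Tensor(fan_in_uniform(rng, (kernel, c_in, c_out), fan_in),
                             requires_grad=True)
        self.bias = Tensor(fan_in_uniform(rng, (c_out,), fan_in), requires_grad=True)
        self.padding = padding
        self.dilation = dilation

    def forward(self, x: Tensor) -> Tensor:
        return x.conv1d(self.weight, self.bias, padding=self.padding,
                        dilation=self.dilation)


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        xn = xc / (var + self.eps).sqrt()
        return xn * self.gamma + self.beta


class Mlp(Module):
    def __init__(self, dim: int, hidden: int, rng: np.random.Generator):
        self.fc1 = Linear(dim, hidden, rng)
        self.fc2 = Linear(hidden, dim, rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).gelu())


class WindowAttention(Module):
    """Multi-head self-attention within non-overlapping 1D windows.

    Relative position bias table has 2*window-1 entries per head, indexed by
    the signed token offset within a window.
    """

    def __init__(self, dim: int, window: int, heads: int, rng: np.random.Generator):
        if dim % heads:
            raise ValueError("dim must be divisible by heads")
        self.dim = dim
        self.window = window
        self.heads = heads
        self.head_dim = dim // heads
        self.qkv = Linear(dim, 3 * dim, rng)
        self.proj = Linear(dim, dim, rng)
        self.rel_bias = Tensor(trunc_normal(rng, (2 * window - 1, heads)),
                               requires_grad=True)
        offs = np.arange(window)[:, None] - np.arange(window)[None, :]
        self.rel_index = offs + window - 1  # (w, w) in [0, 2w-2]

    def forward(self, x: Tensor, mask: np.ndarray | None = None) -> Tensor:
        """x: (B, T, C), T divisible by window.  mask: (n_windows, w, w)
        additive logits mask (0 or NEG_INF) applied per window, or None."""
        b, t, c = x.shape
        w, h, hd = self.window, self.heads, self.head_dim
        if t % w:
            raise ValueError(f"sequence length {t} not divisible by window {w}")
        nw = t // w
        qkv = self.qkv(x)                                   # (B, T, 3C)
        qkv = qkv.reshape(b, nw, w, 3, h, hd)
        qkv = qkv.transpose(3, 0, 1, 4, 2, 5)               # (3, B, nw, h, w, hd)
        q = qkv.slice_first(0)
        k = qkv.slice_first(1)
        v = qkv.slice_first(2)
        attn = (q * (1.0 / np.sqrt(hd))) @ k.transpose(0, 1, 2, 4, 3)  # (B,nw,h,w,w)
        bias = self.rel_bias.gather(self.rel_index)          # (w, w, h)
        attn = attn + bias.transpose(2, 0, 1)                # broadcast (h, w, w)
        if mask is not None:
            attn = attn + mask[None, :, None, :, :]
        attn = attn.softmax(axis=-1)
        self.last_attn = attn.data          # (B, nw, heads, w, w), for inspection
        out = attn @ v                                       # (B, nw, h, w, hd)
        out = out.transpose(0, 1, 3, 2, 4).reshape(b, t, c)
        return self.proj(out)


def _seam_mask(t: int, window: int, shift: int) -> np.ndarray:
    """Additive attention mask for cyclically shifted windows.

    After rolling the sequence left by `shift`, the last window mixes tokens
    from both ends of the sequence; attention between the two segments is
    blocked with a large negative logit.
    """
    seg = np.zeros(t, dtype=int)
    idx = (np.arange(t) + shift) % t
    seg[idx >= t - shift] = 1
    seg = seg.reshape(-1, window)
    mask = np.where(seg[:, :, None] != seg[:, None, :], NEG_INF, 0.0)
    return mask


class SwinLayer(Module):
    """One Swin transformer layer: LN -> (shifted) window MSA -> residual,
    LN -> MLP -> residual."""

    def __init__(self, dim: int, window: int, heads: int, mlp_ratio: float,
                 shift: int, rng: np.random.Generator):
        self.norm1 = LayerNorm(dim)
        self.attn = WindowAttention(dim, window, heads, rng)
        self.norm2 = LayerNorm(dim)
        self.mlp = Mlp(dim, int(dim * mlp_ratio), rng)
        self.shift = shift
        self.window = window

    def forward(self, x: Tensor) -> Tensor:
        b, t, c = x.shape
        h = self.norm1(x)
        if self.shift:
            h = h.roll(-self.shift, axis=1)
            mask = _seam_mask(t, self.window, self.shift)
            h = self.attn(h, mask)
            h = h.roll(self.shift, axis=1)
        else:
            h = self.attn(h, None)
        x = x + h
        return x + self.mlp(self.norm2(x))


class ResidualSwinBlock(Module):
    """RSTB: a stack of STLs (alternating shift) + conv, with a residual add."""

    def __init__(self, dim: int, n_layers: int, window: int, heads: int,
                 mlp_ratio: float, kernel: int, rng: np.random.Generator):
        self.layers = [
            SwinLayer(dim, window, heads, mlp_ratio,
                      shift=(window // 2 if i % 2 else 0), rng=rng)
            for i in range(n_layers)
        ]
        self.conv = Conv1d(dim, dim, kernel, rng)

    def forward(self, x: Tensor) -> Tensor:
        h = x
        for layer in self.layers:
            h = layer(h)
        return x + self.conv(h)
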