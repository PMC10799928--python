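"""Reconstruction networks.

The main network maps a pre-interpolated, low-pass-filtered window of T
samples to the high-frequency window of the same length: a shallow 1D
convolution lifts the signal to C feature channels (shallow feature F_SF), a
stack of residual shifted-window transformer blocks produces the deep feature
F_DF, and a final 1D convolution projects the sum F_SF + F_DF back to one
channel.  There is no upsampling layer — temporal resolution is restored
before the network by Fourier interpolation.

Three reference families are provided for comparison: a SwinIR-style network
(same trunk, consuming the *downsampled* window and ending in a 1D sub-pixel
shuffle upsampler), an EDSR-style residual CNN with upsampler, and a TCN
(dilated causal convolutions, one-sample output).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import h5py
import numpy as np

from .nn.autograd import Tensor, no_grad
from .nn.layers import Module, Conv1d, Linear, ResidualSwinBlock


@dataclass
class ModelConfig:
    """Spk-Recon hyperparameters.  Defaults follow the full-scale network:
    window length 128 samples, 180 feature channels, 6 RSTBs of 6 STLs,
    kernel length 3."""

    T: int = 128
    C: int = 180
    n_rstb: int = 6
    n_stl: int = 6
    kernel: int = 3
    heads: int = 6
    attn_window: int = 8
    mlp_ratio: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        if self.T % self.attn_window:
            raise ValueError(f"T={self.T} must be divisible by attn_window={self.attn_window}")
        if self.C % self.heads:
            raise ValueError(f"C={self.C} must be divisible by heads={self.heads}")
        for name in ("T", "C", "n_rstb", "n_stl", "kernel", "heads", "attn_window"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


@dataclass
class BaselineConfig:
    """family: 'swinir' | 'edsr' | 'tcn'.  M is the upsampling factor for the
    families whose input is the downsampled (not interpolated) window."""

    family: str = "swinir"
    M: int | None = None
    T: int = 128
    C: int = 180
    n_rstb: int = 6
    n_stl: int = 6
    n_resblocks: int = 16
    kernel: int = 3
    heads: int = 6
    attn_window: int = 8
    mlp_ratio: float = 2.0
    n_tcn_blocks: int = 6
    seed: int = 0


class SpkRecon(Module):
    def __init__(self, cfg: ModelConfig):
        cfg.validate()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        self.conv_sf = Conv1d(1, cfg.C, cfg.kernel, rng)
        self.blocks = [
            ResidualSwinBlock(cfg.C, cfg.n_stl, cfg.attn_window, cfg.heads,
                              cfg.mlp_ratio, cfg.kernel, rng)
            for _ in range(cfg.n_rstb)
        ]
        self.conv_out = Conv1d(cfg.C, 1, cfg.kernel, rng)

    def shallow_feature(self, x: Tensor) -> Tensor:
        return self.conv_sf(x)

    def deep_feature(self, f_sf: Tensor) -> Tensor:
        h = f_sf
        for blk in self.blocks:
            h = blk(h)
        return h

    def forward(self, x: Tensor) -> Tensor:
        """x: (B, T, 1) -> (B, T, 1)."""
        if x.shape[1] != self.cfg.T:
            raise ValueError(f"window length {x.shape[1]} != configured T={self.cfg.T}")
        f_sf = self.shallow_feature(x)
        f_df = self.deep_feature(f_sf)
        return self.conv_out(f_sf + f_df)


class _PixelShuffle1d(Module):
    """(B, T, r*C) -> (B, T*r, C): interleaves the r sub-channel groups."""

    def __init__(self, r: int, c_out: int):
        self.r = r
        self.c_out = c_out

    def forward(self, x: Tensor) -> Tensor:
        b, t, rc = x.shape
        return x.reshape(b, t, self.r, self.c_out).reshape(b, t * self.r, self.c_out)


class SwinIR1d(Module):
    """Same transformer trunk, but fed the downsampled window directly and
    ending in a sub-pixel (pixel-shuffle) upsampler of factor M."""

    def __init__(self, cfg: BaselineConfig):
        if cfg.M is None:
            raise ValueError("swinir family requires the upsampling factor M")
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        self.conv_sf = Conv1d(1, cfg.C, cfg.kernel, rng)
        self.blocks = [
            ResidualSwinBlock(cfg.C, cfg.n_stl, cfg.attn_window, cfg.heads,
                              cfg.mlp_ratio, cfg.kernel, rng)
            for _ in range(cfg.n_rstb)
        ]
        self.up_conv = Conv1d(cfg.C, cfg.M * cfg.C, cfg.kernel, rng)
        self.shuffle = _PixelShuffle1d(cfg.M, cfg.C)
        self.conv_out = Conv1d(cfg.C, 1, cfg.kernel, rng)

    def forward(self, x: Tensor) -> Tensor:
        f = self.conv_sf(x)
        h = f
        for blk in self.blocks:
            h = blk(h)
        h = self.shuffle(self.up_conv(f + h))
        return self.conv_out(h)


class _EdsrResBlock(Module):
    def __init__(self, c: int, kernel: int, rng: np.random.Generator):
        self.conv1 = Conv1d(c, c, kernel, rng)
        self.conv2 = Conv1d(c, c, kernel, rng)

    def forward(self, x: Tensor) -> Tensor:
        return x + self.conv2(self.conv1(x).relu())


class Edsr1d(Module):
    """Residual CNN super-resolver: head conv, n_resblocks residual blocks,
    body conv with global skip, sub-pixel upsampler, output conv."""

    def __init__(self, cfg: BaselineConfig):
        if cfg.M is None:
            raise ValueError("edsr family requires the upsampling factor M")
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        self.head = Conv1d(1, cfg.C, cfg.kernel, rng)
        self.body = [_EdsrResBlock(cfg.C, cfg.kernel, rng) for _ in range(cfg.n_resblocks)]
        self.body_conv = Conv1d(cfg.C, cfg.C, cfg.kernel, rng)
        self.up_conv = Conv1d(cfg.C, cfg.M * cfg.C, cfg.kernel, rng)
        self.shuffle = _PixelShuffle1d(cfg.M, cfg.C)
        self.conv_out = Conv1d(cfg.C, 1, cfg.kernel, rng)

    def forward(self, x: Tensor) -> Tensor:
        f = self.head(x)
        h = f
        for blk in self.body:
            h = blk(h)
        h = f + self.body_conv(h)
        return self.conv_out(self.shuffle(self.up_conv(h)))


class _TcnBlock(Module):
    def __init__(self, c_in: int, c: int, kernel: int, dilation: int,
                 rng: np.random.Generator):
        self.conv1 = Conv1d(c_in, c, kernel, rng, padding="causal", dilation=dilation)
        self.conv2 = Conv1d(c, c, kernel, rng, padding="causal", dilation=dilation)
        self.down = Linear(c_in, c, rng) if c_in != c else None

    def forward(self, x: Tensor) -> Tensor:
        h = self.conv2(self.conv1(x).relu()).relu()
        skip = self.down(x) if self.down is not None else x
        return skip + h


class Tcn(Module):
    """Dilated causal convolution stack; predicts the next single sample from
    an interpolated input window (default length 127)."""

    def __init__(self, cfg: BaselineConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        self.blocks = []
        c_in = 1
        for i in range(cfg.n_tcn_blocks):
            self.blocks.append(_TcnBlock(c_in, cfg.C, cfg.kernel, 2**i, rng))
            c_in = cfg.C
        self.head = Linear(cfg.C, 1, rng)

    def forward(self, x: Tensor) -> Tensor:
        """x: (B, T, 1) -> (B, 1, 1), from the last time step."""
        h = x
        for blk in self.blocks:
            h = blk(h)
        last = h.slice_time(h.shape[1] - 1, h.shape[1])
        return self.head(last)


def build_spk_recon(cfg: ModelConfig | None = None) -> SpkRecon:
    return SpkRecon(cfg or ModelConfig())


def build_baseline(cfg: BaselineConfig) -> Module:
    fam = cfg.family.lower()
    if fam == "swinir":
        return SwinIR1d(cfg)
    if fam == "edsr":
        return Edsr1d(cfg)
    if fam == "tcn":
        return Tcn(cfg)
    raise ValueError(f"unknown baseline family {cfg.family!r}")


def forward_window(network: Module, window: np.ndarray) -> np.ndarray:
    """Run one or more windows through a network in inference mode.

    window: (T,) or (B, T); returns the same leading shape.
    """
    w = np.asarray(window, dtype=np.float64)
    squeeze = w.ndim == 1
    if squeeze:
        w = w[None, :]
    with no_grad():
        out = network(Tensor(w[:, :, None])).data[:, :, 0]
    return out[0] if squeeze else out


def save_checkpoint(network: Module, path: str, extra: dict | None = None) -> None:
    """HDF5 checkpoint with the config embedded, plus a JSON config sidecar."""
    cfg = asdict(network.cfg)
    with h5py.File(path, "w") as f:
        f.attrs["config"] = json.dumps(cfg)
        f.attrs["kind"] = type(network).__name__
        g = f.create_group("params")
        for k, v in network.state_dict().items():
            g.create_dataset(k, data=v)
    with open(str(path) + ".json", "w") as f:
        json.dump({"kind": type(network).__name__, "config": cfg}, f, indent=2)


_KINDS = {"SpkRecon": (SpkRecon, ModelConfig),
          "SwinIR1d": (SwinIR1d, BaselineConfig),
          "Edsr1d": (Edsr1d, BaselineConfig),
          "Tcn": (Tcn, BaselineConfig)}


def load_checkpoint(path: str) -> Module:
    with h5py.File(path, "r") as f:
        kind = f.attrs["kind"]
        cfg = json.loads(f.attrs["config"])
        state = {k: v[()] for k, v in f["params"].items()}
    cls, cfg_cls = _KINDS[kind]
    net = cls(cfg_cls(**cfg))
    net.load_state_dict(state)
    return net
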