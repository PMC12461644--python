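"""The generative triad: structure encoder, conditional decoder, discriminator.

The structure encoder extracts a domain-invariant anatomical feature map at
1/4 spatial resolution.  The decoder mirrors it; every convolution inside its
blocks draws per-sample kernels from a hyper-network conditioned on the
domain encoding T, so a single generator renders any prompt-described
appearance.  The discriminator is conditioned on T the same way and scores
overlapping patches at 1/8 resolution (least-squares GAN).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np

from . import nn
from .nn import functional as F
from .nn.tensor import Tensor

__all__ = [
    "TranslatorConfig", "StructureEncoder", "ConditionalDecoder",
    "Discriminator", "Translator", "translate",
]


@dataclass
class TranslatorConfig:
    in_channels: int = 1
    stem_channels: int = 96
    stage_channels: tuple[int, ...] = (192, 384)
    stage_blocks: tuple[int, ...] = (1, 3)
    cond_dim: int = 512
    disc_channels: tuple[int, ...] = (96, 192, 384)
    disc_blocks: int = 4
    hyper_rank: int = 8
    leaky_slope: float = 0.01
    upsample: str = "bilinear"          # bilinear | nearest

    @classmethod
    def tiny(cls, cond_dim: int = 64) -> "TranslatorConfig":
        # channels /8 relative to full size, single block per stage
        return cls(stem_channels=12, stage_channels=(24, 48), stage_blocks=(1, 1),
                   cond_dim=cond_dim, disc_channels=(12, 24, 48), disc_blocks=2)


class _ConvNeXtStage(nn.Module):
    """n blocks with a self-attention block inserted between each two.

    ``min_attn=1`` is used for the deepest stage so reduced single-block
    configurations keep one attention block there (global context on the
    coarsest grid, where it is cheap).
    """

    def __init__(self, channels: int, n_blocks: int, rng: np.random.Generator,
                 min_attn: int = 0):
        super().__init__()
        from .dclip import ConvNeXtBlock
        self.blocks = nn.ModuleList(ConvNeXtBlock(channels, rng) for _ in range(n_blocks))
        self.attns = nn.ModuleList(
            nn.SelfAttention2d(channels, rng)
            for _ in range(max(n_blocks - 1, min_attn)))

    def forward(self, x: Tensor) -> Tensor:
        for i, block in enumerate(self.blocks):
            x = block(x)
            if i < len(self.attns):
                x = self.attns[i](x)
        return x


class StructureEncoder(nn.Module):
    """7x7 stem + two stride-2 stages -> anatomical features at 1/4 resolution."""

    def __init__(self, cfg: TranslatorConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        self.stem = nn.Conv2d(cfg.in_channels, cfg.stem_channels, 7, rng, stride=1)
        self.downsamples = nn.ModuleList([])
        self.stages = nn.ModuleList([])
        c_prev = cfg.stem_channels
        for c, n in zip(cfg.stage_channels, cfg.stage_blocks):
            self.downsamples.items.append(nn.Conv2d(c_prev, c, 2, rng, stride=2, padding=0))
            self.stages.items.append(_ConvNeXtStage(c, n, rng))
            c_prev = c
        self.out_channels = c_prev

    def describe(self) -> dict:
        return {
            "stem": {"kernel": self.stem.kernel, "stride": self.stem.stride,
                     "out_channels": self.stem.c_out},
            "stage_channels": tuple(d.c_out for d in self.downsamples),
            "stage_blocks": tuple(len(s.blocks) for s in self.stages),
            "stage_strides": tuple(d.stride for d in self.downsamples),
        }

    def forward(self, x: np.ndarray | Tensor) -> Tensor:
        x = x if isinstance(x, Tensor) else Tensor(x)
        if x.shape[-1] % 4 or x.shape[-2] % 4:
            raise ValueError("spatial size must be divisible by 4")
        x = self.stem(x)
        for down, stage in zip(self.downsamples, self.stages):
            x = stage(down(x))
        return x


class _HyperConvNeXtBlock(nn.Module):
    """ConvNeXt block whose convolutions are all hyper-generated from T."""

    def __init__(self, channels: int, cond_dim: int, rank: int, rng: np.random.Generator):
        super().__init__()
        self.channels = channels
        self.dwconv = nn.HyperDepthwiseConv2d(channels, 7, cond_dim, rng, rank=rank)
        self.norm = nn.LayerNorm(channels)
        self.pw1 = nn.HyperConv2d(channels, 4 * channels, 1, cond_dim, rng, rank=rank)
        self.pw2 = nn.HyperConv2d(4 * channels, channels, 1, cond_dim, rng, rank=rank)
        self.pw2.base_weight.data *= 0.1
        self.pw2.basis.data *= 0.1

    def forward(self, x: Tensor, cond: Tensor) -> Tensor:
        y = self.dwconv(x, cond)
        y = self.norm(y.transpose(0, 2, 3, 1)).transpose(0, 3, 1, 2)
        y = self.pw1(y, cond).gelu()
        y = self.pw2(y, cond)
        return x + y


class _HyperStage(nn.Module):
    def __init__(self, channels: int, n_blocks: int, cond_dim: int, rank: int,
                 rng: np.random.Generator, min_attn: int = 0):
        super().__init__()
        self.blocks = nn.ModuleList(
            _HyperConvNeXtBlock(channels, cond_dim, rank, rng) for _ in range(n_blocks))
        self.attns = nn.ModuleList(
            nn.SelfAttention2d(channels, rng)
            for _ in range(max(n_blocks - 1, min_attn)))

    def forward(self, x: Tensor, cond: Tensor) -> Tensor:
        for i, block in enumerate(self.blocks):
            x = block(x, cond)
            if i < len(self.attns):
                x = self.attns[i](x)
        return x


class ConditionalDecoder(nn.Module):
    """Mirror of the structure encoder with hyper-convolutions.

    Stride-2 convolutions become 2x nearest upsampling followed by a stride-1
    convolution; the output is passed through LeakyReLU.
    """

    def __init__(self, cfg: TranslatorConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        channels = list(cfg.stage_channels)     # e.g. (192, 384)
        blocks = list(cfg.stage_blocks)
        self.stages = nn.ModuleList([])
        self.upconvs = nn.ModuleList([])
        # deepest stage first, mirrored
        seq = list(zip(channels, blocks))[::-1]
        for i, (c, n) in enumerate(seq):
            self.stages.items.append(_HyperStage(c, n, cfg.cond_dim, cfg.hyper_rank, rng))
            c_next = seq[i + 1][0] if i + 1 < len(seq) else cfg.stem_channels
            self.upconvs.items.append(nn.Conv2d(c, c_next, 3, rng, stride=1))
        self.head = nn.Conv2d(cfg.stem_channels, cfg.in_channels, 7, rng, stride=1)

    def forward(self, phi: Tensor, cond: Tensor) -> Tensor:
        if cond.ndim == 1:
            cond = cond.reshape(1, -1)
        if cond.shape[-1] != self.cfg.cond_dim:
            raise ValueError(
                f"domain encoding dim {cond.shape[-1]} != hyper-network dim "
                f"{self.cfg.cond_dim}")
        x = phi if isinstance(phi, Tensor) else Tensor(phi)
        upsample = (F.upsample_bilinear2x if self.cfg.upsample == "bilinear"
                    else F.upsample_nearest2x)
        for stage, up in zip(self.stages, self.upconvs):
            x = stage(x, cond)
            x = up(upsample(x))
        return self.head(x).leaky_relu(self.cfg.leaky_slope)


class Discriminator(nn.Module):
    """Patch discriminator conditioned on the domain encoding.

    Three kernel-4 stride-2 convolutions, conditional blocks interleaved with
    self-attention, and a 1x1 single-channel head -> score map at 1/8
    resolution.
    """

    def __init__(self, cfg: TranslatorConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        self.stem_convs = nn.ModuleList([])
        c_prev = cfg.in_channels
        for c in cfg.disc_channels:
            self.stem_convs.items.append(nn.Conv2d(c_prev, c, 4, rng, stride=2, padding=1))
            c_prev = c
        self.blocks = nn.ModuleList(
            _HyperConvNeXtBlock(c_prev, cfg.cond_dim, cfg.hyper_rank, rng)
            for _ in range(cfg.disc_blocks))
        self.attns = nn.ModuleList(
            nn.SelfAttention2d(c_prev, rng) for _ in range(cfg.disc_blocks))
        self.head = nn.Conv2d(c_prev, 1, 1, rng, stride=1, padding=0)

    def describe(self) -> dict:
        return {
            "stem_channels": tuple(c.c_out for c in self.stem_convs),
            "stem_kernels": tuple(c.kernel for c in self.stem_convs),
            "stem_strides": tuple(c.stride for c in self.stem_convs),
            "n_cond_blocks": len(self.blocks),
            "head": {"kernel": self.head.kernel, "out_channels": self.head.c_out},
        }

    def forward(self, image: np.ndarray | Tensor, cond: Tensor) -> Tensor:
        x = image if isinstance(image, Tensor) else Tensor(image)
        if x.shape[-1] % 8 or x.shape[-2] % 8:
            raise ValueError("spatial size must be divisible by 8")
        if cond.ndim == 1:
            cond = cond.reshape(1, -1)
        for conv in self.stem_convs:
            x = conv(x).leaky_relu(0.2)
        for block, attn in zip(self.blocks, self.attns):
            x = attn(block(x, cond))
        return self.head(x)


class Translator(nn.Module):
    """Structure encoder + conditional decoder bundle."""

    def __init__(self, cfg: TranslatorConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        self.encoder = StructureEncoder(cfg, rng)
        self.decoder = ConditionalDecoder(cfg, rng)

    def forward(self, x: np.ndarray | Tensor, cond: Tensor) -> Tensor:
        return self.decoder(self.encoder(x), cond)

    def save(self, path) -> None:
        nn.save_checkpoint(path, self.state_dict(), {"cfg": asdict(self.cfg)})

    @classmethod
    def load_from(cls, path) -> "Translator":
        state, meta = nn.load_checkpoint(path)
        cfg = dict(meta["cfg"])
        for key in ("stage_channels", "stage_blocks", "disc_channels"):
            cfg[key] = tuple(cfg[key])
        model = cls(TranslatorConfig(**cfg), np.random.default_rng(0))
        return model.load_state_dict(state)


def translate(slice_2d: np.ndarray, prompt, dclip_model, translator: Translator) -> np.ndarray:
    """Render an input slice into the domain described by ``prompt``.

    The text encoder is used frozen: its embedding is detached before it
    conditions the decoder.
    """
    T = dclip_model.encode_text(prompt).detach()
    x = np.asarray(slice_2d, dtype=np.float32)[None, None]
    out = translator(Tensor(x), T.reshape(1, -1))
    return out.data[0, 0]
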