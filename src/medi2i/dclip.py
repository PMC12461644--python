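"""Contrastive language-image pre-training on medical prompts (dual encoders).

A transformer text encoder and a ConvNeXt image encoder project prompts and
slices into a shared, L2-normalized domain-encoding space.  Pre-training uses
a supervised multi-positive contrastive objective: because several images in
a batch can share a protocol, the label matrix M marks *all* prompt/image
pairs that match under the sentence-subset rule, and each matched pair
contributes a softmax term in both the text->image and image->text
directions (temperature tau = 0.07).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from . import nn
from .nn import functional as F
from .nn.tensor import Tensor, stack
from .prompts import MedicalPrompt, augment_prompt, build_match_matrix
from .tokenizer import BPETokenizer, load_default_tokenizer

__all__ = [
    "TextEncoderConfig", "ImageEncoderConfig", "TextEncoder", "ImageEncoder",
    "ConvNeXtBlock", "DCLIPModel", "dclip_loss", "zero_shot_classify",
    "pretrain_dclip", "zero_shot_accuracy",
]


# ---------------------------------------------------------------------------
# configs
# ---------------------------------------------------------------------------

@dataclass
class TextEncoderConfig:
    layers: int = 12
    width: int = 768
    heads: int = 12
    vocab_size: int = 49152
    max_context: int = 256
    projection_dim: int = 512
    truncate_overlong: bool = False

    @classmethod
    def tiny(cls, vocab_size: int, projection_dim: int = 64) -> "TextEncoderConfig":
        return cls(layers=2, width=64, heads=4, vocab_size=vocab_size,
                   max_context=96, projection_dim=projection_dim)


@dataclass
class ImageEncoderConfig:
    in_channels: int = 1
    stem_kernel: int = 7
    stem_stride: int = 1
    stage_channels: tuple[int, ...] = (96, 192, 384, 768)
    stage_blocks: tuple[int, ...] = (3, 3, 9, 3)
    stage_strides: tuple[int, ...] = (4, 2, 2, 2)
    pool_heads: int = 8
    projection_dim: int = 512

    def __post_init__(self):
        if not (len(self.stage_channels) == len(self.stage_blocks)
                == len(self.stage_strides) == 4):
            raise ValueError("stage tuples must all have length 4")

    @classmethod
    def tiny(cls, projection_dim: int = 64) -> "ImageEncoderConfig":
        return cls(stage_channels=(16, 32, 64, 128), stage_blocks=(1, 1, 1, 1),
                   pool_heads=4, projection_dim=projection_dim)


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------

class ConvNeXtBlock(nn.Module):
    """Depthwise 7x7 conv -> LayerNorm -> 4x pointwise MLP -> residual."""

    def __init__(self, channels: int, rng: np.random.Generator):
        super().__init__()
        self.channels = channels
        self.dwconv = nn.DepthwiseConv2d(channels, 7, rng)
        self.norm = nn.LayerNorm(channels)
        self.pw1 = nn.Linear(channels, 4 * channels, rng)
        self.pw2 = nn.Linear(4 * channels, channels, rng)
        self.pw2.weight.data *= 0.1  # near-identity start

    def forward(self, x: Tensor) -> Tensor:
        y = self.dwconv(x)
        y = y.transpose(0, 2, 3, 1)  # channels-last
        y = self.pw2(self.pw1(self.norm(y)).gelu())
        return x + y.transpose(0, 3, 1, 2)


class TextEncoder(nn.Module):
    """CLIP-style causal transformer; [EOS] activation -> LN -> projection."""

    def __init__(self, cfg: TextEncoderConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        self.token_embedding = nn.Embedding(cfg.vocab_size, cfg.width, rng)
        self.positional_embedding = Tensor(
            (0.01 * rng.normal(size=(cfg.max_context, cfg.width))).astype(np.float32),
            requires_grad=True)
        self.blocks = nn.ModuleList(
            nn.TransformerBlock(cfg.width, cfg.heads, rng, causal=True)
            for _ in range(cfg.layers))
        self.ln_final = nn.LayerNorm(cfg.width)
        self.projection = nn.Linear(cfg.width, cfg.projection_dim, rng, bias=False)

    def describe(self) -> dict:
        return {
            "layers": len(self.blocks),
            "width": self.blocks[0].attn.dim,
            "heads": self.blocks[0].attn.heads,
            "vocab_size": self.token_embedding.n,
            "max_context": self.positional_embedding.shape[0],
            "projection_dim": self.projection.d_out,
        }

    def forward(self, ids: np.ndarray, eos_positions: np.ndarray) -> Tensor:
        """ids: (B, L) padded token ids; returns unit-norm (B, projection_dim)."""
        B, L = ids.shape
        x = self.token_embedding(ids) + self.positional_embedding[:L]
        for block in self.blocks:
            x = block(x)
        x = self.ln_final(x)
        eos = x[np.arange(B), eos_positions]  # (B, width)
        return self.projection(eos).l2_normalize(axis=-1)


class ImageEncoder(nn.Module):
    """ConvNeXt backbone with attention pooling and a projection head."""

    def __init__(self, cfg: ImageEncoderConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        self.stem = nn.Conv2d(cfg.in_channels, cfg.stage_channels[0],
                              cfg.stem_kernel, rng, stride=cfg.stem_stride)
        self.downsamples = nn.ModuleList([])
        self.stages = nn.ModuleList([])
        c_prev = cfg.stage_channels[0]
        for c, n_blocks, s in zip(cfg.stage_channels, cfg.stage_blocks, cfg.stage_strides):
            self.downsamples.items.append(
                nn.Conv2d(c_prev, c, s, rng, stride=s, padding=0))
            self.stages.items.append(
                nn.ModuleList(ConvNeXtBlock(c, rng) for _ in range(n_blocks)))
            c_prev = c
        self.pool = nn.AttentionPool2d(c_prev, cfg.pool_heads, rng)
        self.projection = nn.Linear(c_prev, cfg.projection_dim, rng, bias=False)

    def describe(self) -> dict:
        return {
            "stem": {"kernel": self.stem.kernel, "stride": self.stem.stride,
                     "out_channels": self.stem.c_out},
            "stage_channels": tuple(d.c_out for d in self.downsamples),
            "stage_blocks": tuple(len(s) for s in self.stages),
            "stage_strides": tuple(d.stride for d in self.downsamples),
            "pooling": "attention",
            "pool_heads": self.pool.heads,
            "projection_dim": self.projection.d_out,
        }

    def forward(self, images: np.ndarray | Tensor) -> Tensor:
        """images: (B, C, H, W) -> unit-norm (B, projection_dim)."""
        x = images if isinstance(images, Tensor) else Tensor(images)
        if not np.isfinite(x.data).all():
            raise ValueError("image contains non-finite pixels")
        H = x.shape[-1]
        total_stride = int(np.prod(self.cfg.stage_strides)) * self.cfg.stem_stride
        if H % total_stride:
            raise ValueError(f"spatial size must be divisible by {total_stride}")
        x = self.stem(x)
        for down, stage in zip(self.downsamples, self.stages):
            x = down(x)
            for block in stage:
                x = block(x)
        pooled = self.pool(x)
        return self.projection(pooled).l2_normalize(axis=-1)


# ---------------------------------------------------------------------------
# loss and zero-shot classification
# ---------------------------------------------------------------------------

def dclip_loss(zT, zI, M: np.ndarray, tau: float = 0.07) -> Tensor:
    """Supervised multi-positive contrastive loss.

    ``zT``: (Nt, d) text embeddings (rows of M); ``zI``: (Ni, d) image
    embeddings (columns of M); ``M`` binary match matrix.  Each matched pair
    contributes -log softmax terms in both directions, averaged over the
    matches of its row/column; rows or columns with no match contribute 0.
    """
    if tau <= 0:
        raise ValueError("temperature must be positive")
    zT = zT if isinstance(zT, Tensor) else stack([Tensor(z) for z in zT])
    zI = zI if isinstance(zI, Tensor) else stack([Tensor(z) for z in zI])
    M = np.asarray(M, dtype=float)
    if M.shape != (zT.shape[0], zI.shape[0]):
        raise ValueError("M shape must be (n_text, n_image)")
    logits = (zT @ zI.transpose(1, 0)) * (1.0 / tau)
    ls_rows = logits.log_softmax(axis=1)   # text -> over images
    ls_cols = logits.log_softmax(axis=0)   # image -> over texts
    row_n = np.maximum(M.sum(axis=1, keepdims=True), 1.0)
    col_n = np.maximum(M.sum(axis=0, keepdims=True), 1.0)
    loss = -((Tensor(M / row_n) * ls_rows).sum() + (Tensor(M / col_n) * ls_cols).sum())
    return loss


def zero_shot_classify(image_emb: np.ndarray, candidate_embs: Sequence[np.ndarray]) -> int:
    """Index of the candidate prompt with the largest cosine similarity.

    Ties resolve to the lowest index (argmax convention).
    """
    cands = np.asarray([np.asarray(c, dtype=float) for c in candidate_embs])
    if cands.size == 0:
        raise ValueError("candidate list must be non-empty")
    v = np.asarray(image_emb, dtype=float)
    sims = cands @ v / (np.linalg.norm(cands, axis=1) * np.linalg.norm(v))
    return int(np.argmax(sims))


# ---------------------------------------------------------------------------
# model bundle
# ---------------------------------------------------------------------------

class DCLIPModel(nn.Module):
    """Text + image encoder pair sharing a projection space and a tokenizer."""

    def __init__(self, text_cfg: TextEncoderConfig, image_cfg: ImageEncoderConfig,
                 rng: np.random.Generator, tokenizer: BPETokenizer | None = None):
        super().__init__()
        if text_cfg.projection_dim != image_cfg.projection_dim:
            raise ValueError("text and image projection dims must agree")
        self.tokenizer = tokenizer or load_default_tokenizer()
        self.text_cfg = text_cfg
        self.image_cfg = image_cfg
        self.text_encoder = TextEncoder(text_cfg, rng)
        self.image_encoder = ImageEncoder(image_cfg, rng)

    # -- text ----------------------------------------------------------
    def tokenize(self, prompts: Sequence[MedicalPrompt]) -> tuple[np.ndarray, np.ndarray]:
        all_ids = []
        for p in prompts:
            ids = self.tokenizer.encode(p.text())
            if len(ids) > self.text_cfg.max_context:
                if not self.text_cfg.truncate_overlong:
                    raise ValueError(
                        f"prompt of {len(ids)} tokens exceeds max_context "
                        f"{self.text_cfg.max_context}")
                ids = ids[:self.text_cfg.max_context - 1] + [self.tokenizer.eos_id]
            all_ids.append(ids)
        L = max(len(i) for i in all_ids)
        out = np.full((len(all_ids), L), self.tokenizer.pad_id, dtype=np.int64)
        eos = np.zeros(len(all_ids), dtype=np.int64)
        for b, ids in enumerate(all_ids):
            out[b, :len(ids)] = ids
            eos[b] = len(ids) - 1
        return out, eos

    def encode_text(self, prompts: MedicalPrompt | Sequence[MedicalPrompt]) -> Tensor:
        single = isinstance(prompts, MedicalPrompt)
        batch = [prompts] if single else list(prompts)
        ids, eos = self.tokenize(batch)
        z = self.text_encoder(ids, eos)
        return z[0] if single else z

    def encode_image(self, images: np.ndarray | Tensor) -> Tensor:
        arr = images.data if isinstance(images, Tensor) else np.asarray(images)
        single = arr.ndim == 2
        if single:
            images = arr[None, None]
        elif arr.ndim == 3:
            images = arr[:, None]
        return self.image_encoder(images)[0] if single else self.image_encoder(images)

    # -- persistence ----------------------------------------------------
    def save(self, path) -> None:
        nn.save_checkpoint(path, self.state_dict(), {
            "text_cfg": asdict(self.text_cfg),
            "image_cfg": asdict(self.image_cfg),
            "vocab_hash": self.tokenizer.vocab_hash(),
        })

    @classmethod
    def load_from(cls, path, tokenizer: BPETokenizer | None = None) -> "DCLIPModel":
        state, cfg = nn.load_checkpoint(path)
        text_cfg = TextEncoderConfig(**cfg["text_cfg"])
        icfg = dict(cfg["image_cfg"])
        for key in ("stage_channels", "stage_blocks", "stage_strides"):
            icfg[key] = tuple(icfg[key])
        image_cfg = ImageEncoderConfig(**icfg)
        model = cls(text_cfg, image_cfg, np.random.default_rng(0), tokenizer)
        if model.tokenizer.vocab_hash() != cfg["vocab_hash"]:
            raise ValueError("tokenizer vocabulary does not match checkpoint")
        model.load_state_dict(state)
        return model


# ---------------------------------------------------------------------------
# pre-training
# ---------------------------------------------------------------------------

def pretrain_dclip(corpus: Sequence[tuple[np.ndarray, MedicalPrompt]],
                   text_cfg: TextEncoderConfig, image_cfg: ImageEncoderConfig,
                   epochs: int, batch_size: int, rng: np.random.Generator,
                   lr: float = 1e-4, tau: float = 0.07, drop_prob: float = 0.5,
                   tokenizer: BPETokenizer | None = None,
                   log_path=None,
                   eval_fn=None, keep_best: bool = False) -> tuple[DCLIPModel, list[dict]]:
    """Contrastive pre-training of the dual encoders.

    ``corpus`` holds (2D slice, original prompt) pairs.  Per step, each
    prompt is augmented, the match matrix is built against the originals,
    and one AdamW step minimizes the contrastive loss.  Returns the model
    and a per-epoch history (also written as CSV when ``log_path`` given).
    With ``keep_best`` and an ``eval_fn``, the state with the best evaluation
    score is restored at the end (validation-based model selection).
    """
    corpus = list(corpus)
    if not corpus:
        raise ValueError("empty corpus")
    model = DCLIPModel(text_cfg, image_cfg, rng, tokenizer)
    opt = nn.AdamW(model.parameters(), lr=lr)
    history: list[dict] = []
    best_state, best_score = None, -np.inf
    n = len(corpus)
    for epoch in range(epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            if len(idx) < 2:
                continue
            images = np.stack([corpus[i][0] for i in idx])[:, None]
            originals = [corpus[i][1] for i in idx]
            candidates = [augment_prompt(p, rng, drop_prob=drop_prob) for p in originals]
            M = build_match_matrix(originals, candidates)
            zT = model.encode_text(candidates)
            zI = model.encode_image(Tensor(images.astype(np.float32)))
            loss = dclip_loss(zT, zI, M, tau) / len(idx)
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item())
        row = {"epoch": epoch, "loss": float(np.mean(losses))}
        if eval_fn is not None:
            row["zero_shot_accuracy"] = float(eval_fn(model))
            if keep_best and (best_state is None
                              or row["zero_shot_accuracy"] >= best_score):
                best_score = row["zero_shot_accuracy"]
                best_state = model.state_dict()
        history.append(row)
    if keep_best and eval_fn is not None and best_state is not None:
        model.load_state_dict(best_state)
    if log_path is not None:
        with open(log_path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=list(history[0].keys()))
            writer.writeheader()
            writer.writerows(history)
    return model, history


def zero_shot_accuracy(model: DCLIPModel,
                       samples: Sequence[tuple[np.ndarray, int]],
                       candidate_prompts: Sequence[MedicalPrompt]) -> float:
    """Fraction of slices whose nearest candidate prompt is the true domain."""
    cand_embs = model.encode_text(candidate_prompts).data
    correct = 0
    for image, label in samples:
        emb = model.encode_image(image).data
        correct += zero_shot_classify(emb, cand_embs) == label
    return correct / len(samples)
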