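"""Two-stage training orchestration and model selection.

Stage "init" trains structure encoder + conditional decoder with paired
inner-subject supervision (reconstruction + structure consistency).  Stage
"fine" adds cross-dataset collaborative learning: a triangular consistency
loss through an intermediate domain drawn from another dataset of the same
organ, a least-squares adversarial loss with the prompt-conditioned
discriminator, and a cosine semantic loss against the frozen image encoder.
The best checkpoint is the one maximizing mean validation PSNR.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from . import nn
from .nn.tensor import Tensor
from .dclip import DCLIPModel
from .losses import (LossWeights, adversarial_losses, cosine_semantic_loss,
                     l1_loss, perceptual_loss, pixel_contrastive_loss,
                     downsample_mask, mse_loss, total_loss,
                     FixedProjectionExtractor)
from .metrics import psnr
from .synthetic import SyntheticCorpus, DEFAULT_DOMAINS
from .translation import Translator, TranslatorConfig, Discriminator

__all__ = ["ExperimentConfig", "TrainState", "train_two_stage",
           "select_best_model", "validation_psnr"]


@dataclass
class ExperimentConfig:
    """Printed defaults of the training recipe; desk runs scale counts down."""

    init_epochs: int = 5
    fine_epochs: int = 45
    batch_size: int = 6
    lr: float = 1e-4
    betas: tuple[float, float] = (0.9, 0.999)
    weight_decay: float = 0.01
    image_size: int = 256
    weights: LossWeights = field(default_factory=LossWeights)
    pairs_per_epoch: int = 48           # paired samples drawn per epoch
    pcl_max_pixels: int = 64            # subsample cap for the pixel contrastive term
    adv_trains_encoder: bool = True     # generator adversarial gradient reaches E_phi
    cosine_decay: bool = False          # anneal lr to lr/10 over the schedule
    grad_clip: float | None = None      # optional global gradient-norm ceiling
    seed: int = 0

    @classmethod
    def tiny(cls, **kw) -> "ExperimentConfig":
        """Desk-scale study conditions: 64x64 slices, a shortened schedule
        with a correspondingly larger, cosine-annealed learning rate."""
        defaults = dict(init_epochs=4, fine_epochs=8, image_size=64,
                        pairs_per_epoch=120, lr=1e-3, cosine_decay=True)
        defaults.update(kw)
        return cls(**defaults)

    def lr_at(self, epoch: int) -> float:
        if not self.cosine_decay:
            return self.lr
        n = max(self.init_epochs + self.fine_epochs - 1, 1)
        frac = min(epoch / n, 1.0)
        lo = self.lr / 10.0
        return lo + 0.5 * (self.lr - lo) * (1.0 + np.cos(np.pi * frac))


@dataclass
class TrainState:
    """One checkpoint: epoch, stage, weights, optimizer state, metrics."""

    epoch: int
    stage: str
    val_psnr: float
    losses: dict[str, float]
    translator_state: dict
    disc_state: dict
    opt_state: dict
    disc_opt_state: dict


def _batched_prompts_to_T(dclip: DCLIPModel, prompts,
                          cache: dict | None = None) -> Tensor:
    """Frozen text encodings; prompts are templated so caching by text is
    exact."""
    if cache is None:
        return dclip.encode_text(prompts).detach()
    keys = [p.text() for p in prompts]
    new = {k: p for k, p in zip(keys, prompts) if k not in cache}
    if new:
        z = dclip.encode_text(list(new.values())).data
        for k, v in zip(new, z):
            cache[k] = v
    return Tensor(np.stack([cache[k] for k in keys]))


def _structure_consistency_batch(phi_src: Tensor, phi_tgt: Tensor,
                                 masks0: np.ndarray, tau: float,
                                 rng: np.random.Generator, max_pixels: int) -> Tensor:
    """Batch mean of the structure-consistency loss, with the contrastive term
    evaluated on at most ``max_pixels`` randomly chosen foreground pixels."""
    from .losses import _normalize_channelwise

    B = phi_src.shape[0]
    out = mse_loss(phi_src, phi_tgt)
    for b in range(B):
        mask = downsample_mask(masks0[b], 4)
        ys, xs = np.nonzero(mask)
        if ys.size > max_pixels:
            keep = rng.choice(ys.size, size=max_pixels, replace=False)
            sub = np.zeros_like(mask)
            sub[ys[keep], xs[keep]] = True
            mask = sub
        pcl = pixel_contrastive_loss(
            _normalize_channelwise(phi_src[b]), _normalize_channelwise(phi_tgt[b]),
            mask, tau, check_normalized=False, reduction="mean")
        out = out + pcl / B
    return out


def validation_psnr(corpus: SyntheticCorpus, dclip: DCLIPModel,
                    translator: Translator, split: str = "val",
                    seed: int = 1234, t_cache: dict | None = None) -> float:
    """Mean PSNR of within-dataset translations on center slices."""
    rng = np.random.default_rng(seed)
    inputs, targets, prompts = [], [], []
    translator.eval()
    for subject in corpus.cohort(split):
        domains = corpus.domains_of(subject.dataset)
        samples = corpus.paired_slices(subject, domains, rng, center=True)
        for i, src in enumerate(samples):
            for j, tgt in enumerate(samples):
                if i == j:
                    continue
                inputs.append(src.image)
                targets.append(tgt.image)
                prompts.append(tgt.prompt)
    values = []
    for start in range(0, len(inputs), 8):
        chunk = slice(start, start + 8)
        T = _batched_prompts_to_T(dclip, prompts[chunk], t_cache)
        x = np.stack(inputs[chunk])[:, None].astype(np.float32)
        pred = translator(x, T).data[:, 0]
        values.extend(psnr(p, t) for p, t in zip(pred, targets[chunk]))
    translator.train()
    return float(np.mean(values))


def _draw_training_batch(corpus: SyntheticCorpus, rng: np.random.Generator,
                         batch_size: int, n_intermediates: int = 2):
    """Paired (src, tgt) slices plus unpaired intermediates from another
    dataset of the same organ, drawn within the mini-batch.

    The intermediate domains of the chosen other dataset are traversed (up
    to ``n_intermediates`` of them), so every cross-dataset domain supplies
    collaborative supervision each step.
    """
    train = corpus.cohort("train")
    by_dataset: dict[str, list] = {}
    for s in train:
        by_dataset.setdefault(s.dataset, []).append(s)
    datasets = sorted(by_dataset)
    items = []
    for k in range(batch_size):
        ds = datasets[k % len(datasets)]
        subject = by_dataset[ds][int(rng.integers(len(by_dataset[ds])))]
        domains = list(corpus.domains_of(subject.dataset))
        if len(domains) >= 2:
            pick = rng.permutation(len(domains))[:2]
            pair = (domains[pick[0]], domains[pick[1]])
        else:
            pair = (domains[0], domains[0])
        src, tgt = corpus.paired_slices(subject, pair, rng)
        # intermediates: another dataset, same organ, domains traversed
        other_ds = [d for d in datasets if d != ds] or [ds]
        ods = other_ds[int(rng.integers(len(other_ds)))]
        osub = by_dataset[ods][int(rng.integers(len(by_dataset[ods])))]
        odom = list(corpus.domains_of(ods))
        order = rng.permutation(len(odom))[:n_intermediates]
        intermediates = corpus.paired_slices(osub, tuple(odom[i] for i in order), rng)
        items.append((src, tgt, intermediates))
    return items


def train_two_stage(config: ExperimentConfig, corpus: SyntheticCorpus,
                    dclip: DCLIPModel,
                    translator_cfg: TranslatorConfig | None = None,
                    log_path=None,
                    resume: TrainState | None = None) -> list[TrainState]:
    """Run the init + fine schedule; returns the checkpoint history.

    Per-epoch RNG streams are derived from ``config.seed`` and the epoch
    index, so resuming from a checkpoint reproduces the same subsequent
    loss sequence.
    """
    w = config.weights
    rng0 = np.random.default_rng(config.seed)
    tcfg = translator_cfg or TranslatorConfig.tiny(cond_dim=dclip.text_cfg.projection_dim)
    translator = Translator(tcfg, rng0)
    disc = Discriminator(tcfg, rng0)
    opt = nn.AdamW(translator.parameters(), lr=config.lr, betas=config.betas,
                   weight_decay=config.weight_decay)
    disc_opt = nn.AdamW(disc.parameters(), lr=config.lr, betas=config.betas,
                        weight_decay=config.weight_decay)
    perceptual = FixedProjectionExtractor(seed=0)
    t_cache: dict[str, np.ndarray] = {}

    # the frozen encoders never receive gradients
    for p in dclip.parameters():
        p.requires_grad = False

    start_epoch = 0
    if resume is not None:
        translator.load_state_dict(resume.translator_state)
        disc.load_state_dict(resume.disc_state)
        opt.load_state_dict(resume.opt_state)
        disc_opt.load_state_dict(resume.disc_opt_state)
        start_epoch = resume.epoch + 1

    n_epochs = config.init_epochs + config.fine_epochs
    steps = max(config.pairs_per_epoch // config.batch_size, 1)
    history: list[TrainState] = []
    log_rows = []
    for epoch in range(start_epoch, n_epochs):
        stage = "init" if epoch < config.init_epochs else "fine"
        opt.lr = disc_opt.lr = config.lr_at(epoch)
        rng = np.random.default_rng((config.seed * 100003 + epoch) % (2**31))
        sums: dict[str, float] = {}
        for _ in range(steps):
            batch = _draw_training_batch(corpus, rng, config.batch_size)
            x_src = np.stack([b[0].image for b in batch])[:, None].astype(np.float32)
            x_tgt = np.stack([b[1].image for b in batch])[:, None].astype(np.float32)
            T_src = _batched_prompts_to_T(dclip, [b[0].prompt for b in batch], t_cache)
            T_tgt = _batched_prompts_to_T(dclip, [b[1].prompt for b in batch], t_cache)

            phi_src = translator.encoder(Tensor(x_src))
            phi_tgt = translator.encoder(Tensor(x_tgt))
            x_tgt_rec = translator.decoder(phi_src, T_tgt)
            x_src_rec = translator.decoder(phi_tgt, T_src)

            l_rec = w.lambda_l1 * (l1_loss(x_src_rec, x_src) + l1_loss(x_tgt_rec, x_tgt)) \
                + w.lambda_p * (perceptual_loss(x_src_rec, x_src, perceptual)
                                + perceptual_loss(x_tgt_rec, x_tgt, perceptual))
            masks0 = (x_src[:, 0] > 0) & (x_tgt[:, 0] > 0)
            l_con = _structure_consistency_batch(phi_src, phi_tgt, masks0, w.tau,
                                                 rng, config.pcl_max_pixels)
            components: dict[str, object] = {"rec": l_rec, "con": l_con}

            if stage == "fine":
                phi_for_int = phi_src if config.adv_trains_encoder else phi_src.detach()
                n_int = min(len(b[2]) for b in batch)
                l_tri = l_adv = l_cos = l_d = None
                for j in range(n_int):
                    ints = [b[2][j] for b in batch]
                    x_int = np.stack([s.image for s in ints])[:, None].astype(np.float32)
                    T_int = _batched_prompts_to_T(dclip, [s.prompt for s in ints], t_cache)
                    x_int_fake = translator.decoder(phi_for_int, T_int)
                    x_int_to_tgt = translator.decoder(translator.encoder(x_int_fake), T_tgt)
                    tri_j = w.lambda_l1 * l1_loss(x_int_to_tgt, x_tgt) \
                        + w.lambda_p * perceptual_loss(x_int_to_tgt, x_tgt, perceptual)
                    d_loss, g_loss = adversarial_losses(disc, Tensor(x_int),
                                                        x_int_fake, T_int)
                    fake_emb = dclip.image_encoder(x_int_fake)
                    cos_terms = [cosine_semantic_loss(fake_emb[b], T_int[b].detach())
                                 for b in range(len(batch))]
                    cos_j = sum(cos_terms[1:], cos_terms[0]) / len(batch)
                    l_tri = tri_j if l_tri is None else l_tri + tri_j
                    l_adv = g_loss if l_adv is None else l_adv + g_loss
                    l_cos = cos_j if l_cos is None else l_cos + cos_j
                    l_d = d_loss if l_d is None else l_d + d_loss
                components.update({"tri": l_tri / n_int, "adv": l_adv / n_int,
                                   "cos": l_cos / n_int})
                # one discriminator update per generator step
                d_total = l_d / n_int
                disc_opt.zero_grad()
                d_total.backward()
                if config.grad_clip:
                    disc_opt.clip_grad_norm(config.grad_clip)
                disc_opt.step()
                sums["d_loss"] = sums.get("d_loss", 0.0) + d_total.item()

            gen_total = total_loss(components, stage, w)
            opt.zero_grad()
            gen_total.backward()
            if config.grad_clip:
                opt.clip_grad_norm(config.grad_clip)
            opt.step()

            sums["total"] = sums.get("total", 0.0) + gen_total.item()
            for name, val in components.items():
                sums[name] = sums.get(name, 0.0) + val.item()

        losses = {k: v / steps for k, v in sums.items()}
        losses["stage"] = stage
        val = validation_psnr(corpus, dclip, translator, t_cache=t_cache)
        state = TrainState(
            epoch=epoch, stage=stage, val_psnr=val, losses=losses,
            translator_state=translator.state_dict(),
            disc_state=disc.state_dict(),
            opt_state=opt.state_dict(), disc_opt_state=disc_opt.state_dict())
        history.append(state)
        log_rows.append({"epoch": epoch, "stage": stage, "val_psnr": val,
                         **{k: v for k, v in losses.items() if k != "stage"}})
    if log_path is not None and log_rows:
        keys = sorted({k for row in log_rows for k in row}, key=str)
        with open(log_path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=keys)
            writer.writeheader()
            writer.writerows(log_rows)
    return history


def select_best_model(history: Sequence[TrainState],
                      translator_cfg: TranslatorConfig | None = None) -> TrainState:
    """Checkpoint with the highest validation PSNR; ties go to the latest."""
    if not history:
        raise ValueError("empty history")
    best = history[0]
    for state in history[1:]:
        if state.val_psnr >= best.val_psnr:
            best = state
    return best


def average_top_checkpoints(history: Sequence[TrainState], k: int = 3) -> dict:
    """Uniform weight average of the translator states with the top-k
    validation PSNR (stochastic weight averaging over selected checkpoints;
    smooths the noise of a short schedule)."""
    if not history:
        raise ValueError("empty history")
    top = sorted(history, key=lambda s: (s.val_psnr, s.epoch))[-k:]
    keys = top[0].translator_state.keys()
    return {key: np.mean([s.translator_state[key] for s in top], axis=0)
            for key in keys}
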