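"""Training objectives for prompt-conditioned translation.

Pixel (L1) and perceptual reconstruction on paired slices; structure
consistency between paired feature maps (MSE + a pixel-level contrastive
term on the common foreground); a triangular consistency loss linking
domains across datasets; a least-squares adversarial loss with a
prompt-conditioned discriminator; and a cosine semantic loss tying generated
images to their target domain encoding.  Reductions over pixels are means,
so the loss weights are stable across image sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Callable, Mapping, Sequence

import numpy as np

from .nn.tensor import Tensor, as_tensor

__all__ = [
    "LossWeights", "LossReport", "l1_loss", "mse_loss", "perceptual_loss",
    "reconstruction_loss", "pixel_contrastive_loss", "downsample_mask",
    "structure_consistency_loss", "triangular_loss", "adversarial_losses",
    "cosine_semantic_loss", "total_loss", "make_report",
    "FixedProjectionExtractor",
]


@dataclass(frozen=True)
class LossWeights:
    lambda_l1: float = 10.0
    lambda_p: float = 0.1
    lambda_con: float = 1.0
    lambda_adv: float = 5.0
    lambda_cos: float = 0.1
    tau: float = 0.07

    def __post_init__(self):
        for name, v in asdict(self).items():
            if v <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class LossReport:
    """Named loss components plus the stage totals."""

    components: dict[str, float] = field(default_factory=dict)
    total_init: float | None = None
    total_fine: float | None = None

    def as_row(self) -> dict[str, float]:
        row = dict(self.components)
        if self.total_init is not None:
            row["total_init"] = self.total_init
        if self.total_fine is not None:
            row["total_fine"] = self.total_fine
        return row


def l1_loss(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    if a.shape != b.shape:
        raise ValueError("shape mismatch")
    return (a - b).abs().mean()


def mse_loss(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    if a.shape != b.shape:
        raise ValueError("shape mismatch")
    return ((a - b) ** 2.0).mean()


class FixedProjectionExtractor:
    """Deterministic multi-scale feature extractor for perceptual terms.

    Identity features plus fixed random 3x3 convolution projections at two
    scales; weights are frozen at construction from a seed, so the extractor
    behaves like a (tiny) pre-trained backbone without any download.
    """

    def __init__(self, seed: int = 0, channels: int = 8):
        rng = np.random.default_rng(seed)
        self.w1 = Tensor(rng.normal(0, 0.3, size=(channels, 1, 3, 3)).astype(np.float32))
        self.w2 = Tensor(rng.normal(0, 0.3, size=(channels, channels, 3, 3)).astype(np.float32))

    def __call__(self, x) -> list[Tensor]:
        from .nn import functional as F
        x = as_tensor(x)
        if x.ndim == 2:
            x = x.reshape(1, 1, *x.shape)
        elif x.ndim == 3:
            x = x.reshape(x.shape[0], 1, *x.shape[1:])
        f1 = F.conv2d(x, self.w1, stride=1, padding=1).leaky_relu(0.2)
        f2 = F.conv2d(f1, self.w2, stride=2, padding=1).leaky_relu(0.2)
        return [x, f1, f2]


def perceptual_loss(a, b, extractor: Callable[..., Sequence[Tensor]]) -> Tensor:
    """Sum over extractor layers of the mean squared feature difference."""
    fa, fb = extractor(a), extractor(b)
    out = None
    for la, lb in zip(fa, fb):
        term = mse_loss(la, lb)
        out = term if out is None else out + term
    return out


def reconstruction_loss(x_src, x_tgt, x_src_rec, x_tgt_rec,
                        perceptual: Callable, w: LossWeights) -> Tensor:
    """Paired supervision: L1 + perceptual on both translation directions."""
    pixel = l1_loss(x_src_rec, x_src) + l1_loss(x_tgt_rec, x_tgt)
    percep = perceptual_loss(x_src_rec, x_src, perceptual) + \
        perceptual_loss(x_tgt_rec, x_tgt, perceptual)
    return w.lambda_l1 * pixel + w.lambda_p * percep


def pixel_contrastive_loss(p, q, mask: np.ndarray, tau: float = 0.07,
                           check_normalized: bool = True,
                           reduction: str = "sum") -> Tensor:
    """Symmetric per-pixel InfoNCE over the masked feature pixels.

    ``p``/``q``: (C, h, w) per-pixel L2-normalized feature maps; ``mask``
    binary (h, w).  Every masked pixel is a positive with its counterpart in
    the other map; all masked pixels serve as negatives.  Empty mask -> 0.
    ``reduction``: "sum" is the literal formula; "mean" divides by the pixel
    count (used inside training so the weight of the term does not scale
    with the foreground area).
    """
    p, q = as_tensor(p), as_tensor(q)
    if p.shape != q.shape:
        raise ValueError("feature shapes differ")
    mask = np.asarray(mask).astype(bool)
    if mask.shape != p.shape[1:]:
        raise ValueError("mask spatial grid mismatch")
    if check_normalized:
        for t in (p, q):
            norms = np.sqrt((t.data**2).sum(axis=0))[mask]
            if norms.size and not np.allclose(norms, 1.0, atol=1e-4):
                raise ValueError("features must be per-pixel L2-normalized")
    ys, xs = np.nonzero(mask)
    if ys.size == 0:
        return Tensor(0.0)
    pm = p[(slice(None), ys, xs)]            # (C, N)
    qm = q[(slice(None), ys, xs)]
    logits = (pm.transpose(1, 0) @ qm) * (1.0 / tau)   # (N, N): p_i . q_j
    n = ys.size
    diag = (np.arange(n), np.arange(n))
    loss_pq = -logits.log_softmax(axis=1)[diag].sum()
    loss_qp = -logits.transpose(1, 0).log_softmax(axis=1)[diag].sum()
    out = loss_pq + loss_qp
    if reduction == "mean":
        out = out / n
    elif reduction != "sum":
        raise ValueError("reduction must be 'sum' or 'mean'")
    return out


def downsample_mask(mask: np.ndarray, factor: int = 4) -> np.ndarray:
    """Max-pool a binary mask: a block is foreground if any pixel in it is."""
    mask = np.asarray(mask).astype(bool)
    h, w = mask.shape
    if h % factor or w % factor:
        raise ValueError("mask size must be divisible by the factor")
    return mask.reshape(h // factor, factor, w // factor, factor).any(axis=(1, 3))


def _normalize_channelwise(phi: Tensor) -> Tensor:
    """Channel-wise L2 per spatial location, (C,h,w)."""
    norm = (phi * phi).sum(axis=0, keepdims=True).sqrt()
    return phi / (norm + 1e-8)


def structure_consistency_loss(phi_src, phi_tgt, mask0: np.ndarray,
                               tau: float = 0.07) -> Tensor:
    """MSE on raw feature maps + pixel contrastive loss on normalized ones.

    ``mask0`` is the image-resolution common foreground (both inputs > 0);
    it is max-pool downsampled by 4 to the feature grid.
    """
    phi_src, phi_tgt = as_tensor(phi_src), as_tensor(phi_tgt)
    if phi_src.shape != phi_tgt.shape:
        raise ValueError("feature shapes differ")
    mse = mse_loss(phi_src, phi_tgt)
    mask = downsample_mask(mask0, 4)
    pcl = pixel_contrastive_loss(_normalize_channelwise(phi_src),
                                 _normalize_channelwise(phi_tgt),
                                 mask, tau, check_normalized=False)
    return mse + pcl


def triangular_loss(x_int_to_tgt, x_tgt, perceptual: Callable, w: LossWeights) -> Tensor:
    """Cross-dataset consistency: round-trip through an intermediate domain."""
    return w.lambda_l1 * l1_loss(x_int_to_tgt, x_tgt) + \
        w.lambda_p * perceptual_loss(x_int_to_tgt, x_tgt, perceptual)


def adversarial_losses(discriminator, x_real, x_fake, T) -> tuple[Tensor, Tensor]:
    """Least-squares adversarial pair.

    d_loss = mean((D(real,T)-1)^2) + mean(D(fake,T)^2) with the fake detached;
    g_loss = mean((D(fake,T)-1)^2).
    """
    x_fake_t = as_tensor(x_fake)
    d_real = discriminator(x_real, T)
    d_fake_detached = discriminator(x_fake_t.detach(), T)
    d_loss = ((d_real - 1.0) ** 2.0).mean() + (d_fake_detached ** 2.0).mean()
    d_fake = discriminator(x_fake_t, T)
    g_loss = ((d_fake - 1.0) ** 2.0).mean()
    return d_loss, g_loss


def cosine_semantic_loss(fake_image_emb, T_int) -> Tensor:
    """Negative cosine similarity between a generated image's frozen-encoder
    embedding and its target domain encoding."""
    a, b = as_tensor(fake_image_emb), as_tensor(T_int)
    na = float(np.linalg.norm(a.data))
    nb = float(np.linalg.norm(b.data))
    if na == 0.0 or nb == 0.0:
        raise ValueError("zero vector in cosine loss")
    return -(a * b).sum() / ((a * a).sum().sqrt() * (b * b).sum().sqrt())


def make_report(components: Mapping[str, float], stage: str,
                w: LossWeights) -> LossReport:
    """LossReport with the stage total(s) populated from scalar components."""
    vals = {k: float(v) for k, v in components.items()}
    report = LossReport(components=vals)
    report.total_init = float(total_loss(vals, "init", w))
    if stage == "fine":
        report.total_fine = float(total_loss(vals, "fine", w))
    return report


_STAGE_COMPONENTS = {
    "init": ("rec", "con"),
    "fine": ("rec", "con", "tri", "adv", "cos"),
}


def total_loss(components: Mapping[str, object], stage: str, w: LossWeights):
    """Weighted stage totals.

    init: rec + lambda_con * con
    fine: rec + lambda_con * con + tri + lambda_adv * adv + lambda_cos * cos
    Works on floats or autodiff tensors alike.
    """
    if stage not in _STAGE_COMPONENTS:
        raise ValueError(f"unknown stage {stage!r}")
    missing = [k for k in _STAGE_COMPONENTS[stage] if k not in components]
    if missing:
        raise KeyError(f"missing loss components for stage {stage!r}: {missing}")
    total = components["rec"] + w.lambda_con * components["con"]
    if stage == "fine":
        total = total + components["tri"] + w.lambda_adv * components["adv"] \
            + w.lambda_cos * components["cos"]
    return total
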