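"""Image-quality and segmentation metrics.

PSNR, windowed SSIM (uniform 7x7 window, constants c1=1e-4 / c2=9e-4 for a
unit intensity range), a layer-summed perceptual distance with a pluggable
feature backbone, Dice overlap, average symmetric surface distance, and the
rank-statistic AUC.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import ndimage
from scipy.stats import rankdata

__all__ = [
    "MetricResult", "psnr", "ssim", "lpips", "dsc", "assd", "auc",
    "mask_contour", "evaluate_pairs", "summarize",
]


@dataclass
class MetricResult:
    name: str
    value: float
    per_case: list[float] = field(default_factory=list)

    @property
    def sd(self) -> float:
        return float(np.std(self.per_case)) if self.per_case else 0.0

    def __str__(self):
        return f"{self.name}: {self.value:.4g} ± {self.sd:.4g}"


def psnr(x_hat: np.ndarray, x: np.ndarray, r: float = 1.0) -> float:
    """10*log10(R^2 / MSE) in dB; identical inputs yield +inf."""
    x_hat, x = np.asarray(x_hat, float), np.asarray(x, float)
    if x_hat.shape != x.shape:
        raise ValueError("shape mismatch")
    mse = float(np.mean((x_hat - x) ** 2))
    if mse == 0.0:
        return math.inf
    return 10.0 * math.log10(r * r / mse)


def ssim(x_hat: np.ndarray, x: np.ndarray, window: int = 7,
         c1: float = 0.0001, c2: float = 0.0009) -> float:
    """Mean windowed structural similarity (uniform window, population moments).

    The constants assume an intensity range of 1.  The map is averaged over
    windows fully inside the image.
    """
    a, b = np.asarray(x_hat, float), np.asarray(x, float)
    if a.shape != b.shape:
        raise ValueError("shape mismatch")
    if window > min(a.shape):
        raise ValueError("window larger than image")
    uf = lambda z: ndimage.uniform_filter(z, size=window, mode="constant")
    mu_a, mu_b = uf(a), uf(b)
    var_a = uf(a * a) - mu_a**2
    var_b = uf(b * b) - mu_b**2
    cov = uf(a * b) - mu_a * mu_b
    num = (2 * mu_a * mu_b + c1) * (2 * cov + c2)
    den = (mu_a**2 + mu_b**2 + c1) * (var_a + var_b + c2)
    smap = num / den
    pad = window // 2
    core = smap[tuple(slice(pad, s - pad) for s in smap.shape)]
    return float(core.mean())


def lpips(x_hat: np.ndarray, x: np.ndarray,
          extractor: Callable | None = None) -> float:
    """Layer-summed perceptual distance: sum_l mean((F_l(a) - F_l(b))^2).

    The feature backbone is pluggable; the default is the deterministic
    fixed-projection extractor, so the metric runs without any download.
    """
    from .losses import FixedProjectionExtractor, perceptual_loss

    extractor = extractor or FixedProjectionExtractor(seed=0)
    return float(perceptual_loss(np.asarray(x_hat, np.float32),
                                 np.asarray(x, np.float32), extractor).item())


def _check_binary(m: np.ndarray) -> np.ndarray:
    arr = np.asarray(m)
    vals = np.unique(arr)
    if not np.isin(vals, (0, 1, True, False)).all():
        raise ValueError("mask must be binary")
    return arr.astype(bool)


def dsc(mask_hat: np.ndarray, mask: np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|); two empty masks count as 1."""
    a, b = _check_binary(mask_hat), _check_binary(mask)
    if a.shape != b.shape:
        raise ValueError("shape mismatch")
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(a, b).sum() / denom)


def mask_contour(mask: np.ndarray) -> np.ndarray:
    """8-connectivity border pixels of a binary mask."""
    m = _check_binary(mask)
    interior = ndimage.binary_erosion(m, structure=np.ones((3,) * m.ndim))
    return m & ~interior


def assd(mask_hat: np.ndarray, mask: np.ndarray,
         spacing: Sequence[float] | None = None) -> float:
    """Average symmetric surface distance between mask contours.

    Exact Euclidean distance transforms give each contour point's distance to
    the nearest point of the other contour, in physical units.
    """
    a, b = _check_binary(mask_hat), _check_binary(mask)
    if a.shape != b.shape:
        raise ValueError("shape mismatch")
    if not a.any() or not b.any():
        raise ValueError("masks must be non-empty")
    spacing = tuple(spacing) if spacing is not None else (1.0,) * a.ndim
    ca, cb = mask_contour(a), mask_contour(b)
    dist_to_a = ndimage.distance_transform_edt(~ca, sampling=spacing)
    dist_to_b = ndimage.distance_transform_edt(~cb, sampling=spacing)
    total = dist_to_b[ca].sum() + dist_to_a[cb].sum()
    return float(total / (ca.sum() + cb.sum()))


def auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Rank-statistic AUC: (sum of positive ranks - P(P+1)/2) / (P*N).

    Ties receive mid-ranks.
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels).astype(bool)
    p = int(labels.sum())
    n = int((~labels).sum())
    if p == 0 or n == 0:
        raise ValueError("need at least one positive and one negative sample")
    ranks = rankdata(scores)
    return float((ranks[labels].sum() - p * (p + 1) / 2.0) / (p * n))


def evaluate_pairs(pairs: Sequence[tuple[np.ndarray, np.ndarray]],
                   extractor: Callable | None = None) -> dict[str, MetricResult]:
    """Per-case PSNR/SSIM/perceptual distance over (prediction, reference) pairs."""
    rows = {"psnr": [], "ssim": [], "lpips": []}
    for pred, ref in pairs:
        rows["psnr"].append(psnr(pred, ref))
        rows["ssim"].append(ssim(pred, ref))
        rows["lpips"].append(lpips(pred, ref, extractor))
    return {name: MetricResult(name, float(np.mean(vals)), vals)
            for name, vals in rows.items()}


def summarize(results: dict[str, MetricResult]) -> str:
    return "\n".join(str(r) for r in results.values())
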