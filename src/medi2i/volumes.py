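"""Volume reading/writing, intensity normalization, resampling, slice sampling.

Intensities are normalized as N(X) = (max(X, Rmin) - Rmin) / RX with
modality-specific constants: Rmin = 0 for MRI and -1024 for CT/CBCT; RX is
the 99.5th percentile of the volume for MRI, 3000 for CT and 1500 for CBCT
(no upper clipping).  Volumes are resampled to organ-specific spacing, then
padded or randomly cropped to a cube from which 2D slices are drawn in a
uniformly random plane; paired volumes of one subject share crop offsets,
plane, and slice index so supervision stays aligned.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace as dc_replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .prompts import KeywordSet, MedicalPrompt, extract_keywords, render_prompt

__all__ = [
    "VolumeRecord", "SliceSample", "PLANES",
    "normalize_intensity", "resample_volume",
    "draw_slice_spec", "extract_slice", "sample_slice", "sample_paired_slices",
    "read_nifti", "write_nifti", "read_manifest", "load_volume",
]

PLANES = ("axial", "coronal", "sagittal")

_RMIN = {"MRI": 0.0, "CT": -1024.0, "CBCT": -1024.0}
_RX_FIXED = {"CT": 3000.0, "CBCT": 1500.0}
_MRI_PERCENTILE = 99.5

_ORGAN_SPACING = {
    "brain": (1.0, 1.0, 1.0),
    "breast": (1.0, 1.0, 1.0),
    "abdomen": (2.5, 1.0, 1.0),
    "pelvis": (2.5, 1.0, 1.0),
}


@dataclass
class VolumeRecord:
    voxels: np.ndarray
    spacing: tuple[float, float, float]
    modality: str                      # MRI | CT | CBCT
    organ: str
    keywords: KeywordSet
    subject_key: str = ""
    dataset_key: str = ""
    pairing_key: str = ""
    affine: np.ndarray | None = None

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be a 3D array")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")
        if self.modality not in _RMIN:
            raise ValueError(f"unknown modality {self.modality!r}")


@dataclass
class SliceSample:
    image: np.ndarray                  # (size, size), finite, >= 0
    plane: str
    prompt: MedicalPrompt
    dataset_key: str = ""
    subject_key: str = ""
    pairing_key: str = ""


def normalize_intensity(volume: VolumeRecord,
                        percentile: float = _MRI_PERCENTILE,
                        include_background: bool = True) -> VolumeRecord:
    """Apply the modality-specific intensity normalization.

    MRI: RX is the given percentile of the volume (by default over all
    voxels, background included); CT/CBCT use fixed ranges.  Values above RX
    are passed through (>1), the lower bound is clamped.
    """
    x = np.asarray(volume.voxels, dtype=np.float64)
    if not np.isfinite(x).all():
        raise ValueError("voxels must be finite")
    rmin = _RMIN[volume.modality]
    if volume.modality == "MRI":
        ref = x if include_background else x[x > 0]
        rx = float(np.percentile(ref, percentile))
    else:
        rx = _RX_FIXED[volume.modality]
    if rx <= 0:
        raise ValueError("degenerate volume: normalization range is not positive")
    out = (np.maximum(x, rmin) - rmin) / rx
    return dc_replace(volume, voxels=out)


def resample_volume(volume: VolumeRecord, organ: str | None = None) -> VolumeRecord:
    """Trilinear resampling to the organ's target spacing."""
    from scipy.ndimage import zoom

    organ = (organ or volume.organ).lower()
    if organ not in _ORGAN_SPACING:
        raise ValueError(f"no target spacing defined for organ {organ!r}")
    target = _ORGAN_SPACING[organ]
    if tuple(volume.spacing) == target:
        return volume
    factors = tuple(s / t for s, t in zip(volume.spacing, target))
    out = zoom(np.asarray(volume.voxels, dtype=np.float64), factors, order=1)
    return dc_replace(volume, voxels=out, spacing=target)


# ---------------------------------------------------------------------------
# slice sampling
# ---------------------------------------------------------------------------

def draw_slice_spec(shape: Sequence[int], rng: np.random.Generator,
                    size: int = 256, center: bool = False) -> dict:
    """Random crop/pad offsets, plane, and slice index for one subject.

    The same spec applied to every paired volume of the subject keeps the
    supervision spatially aligned.
    """
    offsets = []
    for dim in shape:
        span = abs(dim - size)
        if span == 0 or center:
            offsets.append(span // 2)
        else:
            offsets.append(int(rng.integers(0, span + 1)))
    plane = int(rng.integers(3)) if not center else 0
    index = size // 2 if center else int(rng.integers(size))
    return {"offsets": tuple(offsets), "plane": PLANES[plane], "index": index,
            "size": size}


def _fit_axis(arr: np.ndarray, axis: int, size: int, offset: int) -> np.ndarray:
    dim = arr.shape[axis]
    if dim == size:
        return arr
    if dim > size:                      # crop
        sl = [slice(None)] * 3
        sl[axis] = slice(offset, offset + size)
        return arr[tuple(sl)]
    pad = [(0, 0)] * 3                  # pad with zeros
    pad[axis] = (offset, size - dim - offset)
    return np.pad(arr, pad)


def extract_slice(volume: VolumeRecord, spec: Mapping) -> SliceSample:
    """Apply a slice spec: pad/crop to a cube, cut the requested plane/index."""
    size = spec["size"]
    cube = np.asarray(volume.voxels, dtype=np.float64)
    for axis, off in enumerate(spec["offsets"]):
        cube = _fit_axis(cube, axis, size, off)
    axis = PLANES.index(spec["plane"])
    image = np.take(cube, spec["index"], axis=axis)
    keywords = dc_replace(volume.keywords, plane=spec["plane"])
    prompt = render_prompt(keywords, subject_key=volume.subject_key,
                           domain_key=volume.pairing_key)
    return SliceSample(image=image, plane=spec["plane"], prompt=prompt,
                       dataset_key=volume.dataset_key,
                       subject_key=volume.subject_key,
                       pairing_key=volume.pairing_key)


def sample_slice(volume: VolumeRecord, rng: np.random.Generator,
                 size: int = 256, center: bool = False) -> SliceSample:
    spec = draw_slice_spec(volume.voxels.shape, rng, size=size, center=center)
    return extract_slice(volume, spec)


def sample_paired_slices(volumes: Sequence[VolumeRecord], rng: np.random.Generator,
                         size: int = 256, center: bool = False) -> list[SliceSample]:
    """One spec, many aligned volumes (same subject, different domains)."""
    shapes = {v.voxels.shape for v in volumes}
    if len(shapes) != 1:
        raise ValueError("paired volumes must share a shape")
    spec = draw_slice_spec(volumes[0].voxels.shape, rng, size=size, center=center)
    return [extract_slice(v, spec) for v in volumes]


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_nifti(path, modality: str, organ: str, keywords: KeywordSet,
               subject_key: str = "", dataset_key: str = "",
               pairing_key: str = "") -> VolumeRecord:
    import nibabel as nib

    img = nib.load(str(path))
    voxels = np.asanyarray(img.dataobj).astype(np.float64)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return VolumeRecord(voxels=voxels, spacing=spacing, modality=modality,
                        organ=organ, keywords=keywords, subject_key=subject_key,
                        dataset_key=dataset_key, pairing_key=pairing_key,
                        affine=np.asarray(img.affine))


def write_nifti(volume: VolumeRecord, path) -> None:
    import nibabel as nib

    affine = volume.affine if volume.affine is not None else \
        np.diag(list(volume.spacing) + [1.0])
    img = nib.Nifti1Image(np.asarray(volume.voxels, dtype=np.float32), affine)
    img.header.set_zooms(volume.spacing)
    nib.save(img, str(path))


def read_manifest(path):
    """Dataset manifest CSV: path, organ, modality, subject, dataset,
    pairing_key, sidecar."""
    import pandas as pd

    return pd.read_csv(path, dtype=str).fillna("")


def load_volume(row: Mapping[str, str], root=None) -> VolumeRecord:
    """Load one manifest row: NIfTI voxels + JSON keyword sidecar."""
    root = Path(root) if root is not None else Path(".")
    sidecar = json.loads((root / row["sidecar"]).read_text()) if row.get("sidecar") else {}
    keywords = extract_keywords({}, overrides=sidecar)
    return read_nifti(root / row["path"], modality=row["modality"],
                      organ=row["organ"], keywords=keywords,
                      subject_key=row["subject"], dataset_key=row["dataset"],
                      pairing_key=row.get("pairing_key", ""))
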