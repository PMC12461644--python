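"""Synthetic multi-dataset, multi-domain phantom corpus.

Each subject is a smooth random 3D "anatomy": nested tissue shells
(rim / subcutaneous-fat-like ring / parenchyma) plus a focal lesion, encoded
as a label map shared by all of the subject's domains.  A domain is a named
bundle of prompt keywords and appearance operators applied to that label
map: a per-class intensity lookup for the pulse sequence, a lesion
enhancement for contrast agent, fat-signal suppression, outer-rim zeroing
(skull-removal-like masking), and additive Gaussian noise.  Prompt attribute
and appearance operator correspond one-to-one, so held-out attribute
combinations (zero-shot domains) are renderable without appearing in
training.  Within a dataset, domains are spatially aligned (paired); across
datasets, subjects are distinct but share the organ.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace as dc_replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .prompts import KeywordSet, render_prompt
from .volumes import (PLANES, SliceSample, VolumeRecord, sample_paired_slices,
                      write_nifti)

__all__ = [
    "BACKGROUND", "RIM", "FAT", "PARENCHYMA", "LESION",
    "SubjectStructure", "DomainSpec", "SEQUENCE_LOOKUPS", "domain_from_attributes",
    "DEFAULT_DOMAINS", "CorpusConfig", "SyntheticCorpus",
    "generate_structure", "render_domain", "build_corpus", "write_corpus",
]

BACKGROUND, RIM, FAT, PARENCHYMA, LESION = 0, 1, 2, 3, 4

# per-class intensity lookup tables per pulse sequence (rim, fat, parenchyma, lesion)
SEQUENCE_LOOKUPS: dict[str, dict[int, float]] = {
    "T1": {RIM: 0.90, FAT: 0.85, PARENCHYMA: 0.55, LESION: 0.35},
    "T2": {RIM: 0.25, FAT: 0.70, PARENCHYMA: 0.45, LESION: 0.85},
    "FLAIR": {RIM: 0.35, FAT: 0.60, PARENCHYMA: 0.30, LESION: 0.95},
}

_SEQUENCE_KEYWORDS = {
    "T1": "T1-weighted",
    "T2": "T2-weighted",
    "FLAIR": "T2-weighted-fluid-attenuated inversion recovery",
}


@dataclass(frozen=True)
class SubjectStructure:
    """Shared tissue label map of one subject (identical across domains)."""

    labels: np.ndarray
    seed: int

    def foreground(self) -> np.ndarray:
        return self.labels > BACKGROUND


@dataclass(frozen=True)
class DomainSpec:
    """A named appearance domain: prompt keywords + ordered appearance ops.

    Supported ops (applied in order): ("lookup", sequence_name),
    ("contrast", factor), ("fatsat", factor), ("skullstrip", None),
    ("smooth", sigma), ("noise", sigma).
    """

    name: str
    keywords: KeywordSet
    ops: tuple[tuple[str, object], ...]

    def prompt(self, subject_key: str = "", plane: str = "axial"):
        kw = dc_replace(self.keywords, plane=plane)
        return render_prompt(kw, subject_key=subject_key, domain_key=self.name)


def domain_from_attributes(name: str, sequence: str, fatsat: bool = False,
                           contrast: bool = False, skullstrip: bool = False,
                           noise_sigma: float = 0.02, smooth_sigma: float = 0.7,
                           scanner: str | None = None) -> DomainSpec:
    """Build a DomainSpec whose keywords and operators correspond one-to-one."""
    if sequence not in SEQUENCE_LOOKUPS:
        raise ValueError(f"unknown sequence {sequence!r}")
    preprocess = []
    if fatsat:
        preprocess.append("fat saturation")
    if skullstrip:
        preprocess.append("skull removal")
    keywords = KeywordSet(
        organ="brain", modality="magnetic resonance imaging", plane="axial",
        sequence=_SEQUENCE_KEYWORDS[sequence],
        contrast="Gadolinium" if contrast else None,
        preprocess=" and ".join(preprocess) or None,
        manufacturer=scanner,
    )
    ops: list[tuple[str, object]] = [("lookup", sequence)]
    if contrast:
        ops.append(("contrast", 1.4))
    if fatsat:
        ops.append(("fatsat", 0.15))
    if skullstrip:
        ops.append(("skullstrip", None))
    ops.append(("smooth", smooth_sigma))
    ops.append(("noise", noise_sigma))
    return DomainSpec(name=name, keywords=keywords, ops=tuple(ops))


DEFAULT_DOMAINS: dict[str, DomainSpec] = {
    "T1": domain_from_attributes("T1", "T1", scanner="Philips"),
    "T2": domain_from_attributes("T2", "T2", scanner="Philips"),
    "T1fs": domain_from_attributes("T1fs", "T1", fatsat=True, scanner="Siemens"),
    "FLAIR": domain_from_attributes("FLAIR", "FLAIR", scanner="Siemens"),
    # held-out attribute combination for zero-shot translation
    "T2fs": domain_from_attributes("T2fs", "T2", fatsat=True, scanner="Siemens"),
}


def generate_structure(seed: int, size: int = 64) -> SubjectStructure:
    """Smooth random blob anatomy with nested rim/fat/parenchyma + lesion."""
    if size < 32:
        raise ValueError("size must be >= 32")
    rng = np.random.default_rng(seed)
    grid = np.stack(np.meshgrid(*([np.arange(size)] * 3), indexing="ij"))
    center = size / 2 + rng.uniform(-0.03, 0.03, size=3) * size
    radii = size * rng.uniform(0.36, 0.44, size=3)
    dist = np.sqrt(sum(((grid[i] - center[i]) / radii[i]) ** 2 for i in range(3)))
    bumps = gaussian_filter(rng.normal(size=(size,) * 3), sigma=size / 8)
    bumps = bumps / (np.abs(bumps).max() + 1e-9) * 0.08
    r = dist + bumps                     # perturbed normalized radius
    labels = np.zeros((size,) * 3, dtype=np.int8)
    labels[r < 1.0] = RIM
    labels[r < 0.88] = FAT
    labels[r < 0.74] = PARENCHYMA
    # focal lesion inside the parenchyma
    offset = rng.uniform(-0.25, 0.25, size=3) * size
    lesion_center = center + offset
    lesion_radius = size * rng.uniform(0.08, 0.12)
    ldist = np.sqrt(sum((grid[i] - lesion_center[i]) ** 2 for i in range(3)))
    labels[(ldist < lesion_radius) & (labels == PARENCHYMA)] = LESION
    return SubjectStructure(labels=labels, seed=seed)


def render_domain(structure: SubjectStructure | np.ndarray, domain: DomainSpec,
                  rng: np.random.Generator | None = None,
                  skip_noise: bool = False) -> np.ndarray:
    """Apply a domain's appearance operators to a label map; output in [0, 1].

    Works on 2D or 3D label arrays; geometry (foreground support) is shared
    across all domains of a subject.  ``skip_noise`` renders the clean image
    (the additive noise is independent per voxel, so it may equivalently be
    drawn later on extracted slices).
    """
    labels = structure.labels if isinstance(structure, SubjectStructure) else structure
    labels = np.asarray(labels)
    body = labels > BACKGROUND
    image = np.zeros(labels.shape, dtype=np.float64)
    for op, arg in domain.ops:
        if op == "lookup":
            table = SEQUENCE_LOOKUPS[arg]
            for cls, value in table.items():
                image[labels == cls] = value
        elif op == "contrast":
            image[labels == LESION] *= float(arg)
        elif op == "fatsat":
            image[labels == FAT] *= float(arg)
        elif op == "skullstrip":
            image[labels == RIM] = 0.0
            body = body & (labels != RIM)
        elif op == "smooth":
            image = gaussian_filter(image, sigma=float(arg))
            image[~body] = 0.0           # keep background support exact
        elif op == "noise":
            if rng is not None and float(arg) > 0 and not skip_noise:
                image[body] += rng.normal(0.0, float(arg), size=int(body.sum()))
        else:
            raise ValueError(f"unknown appearance operator {op!r}")
    return np.clip(image, 0.0, 1.0)


# ---------------------------------------------------------------------------
# corpus
# ---------------------------------------------------------------------------

@dataclass
class CorpusConfig:
    """Layout of the synthetic study: datasets with paired domain sets."""

    datasets: Mapping[str, tuple[str, ...]] = field(default_factory=lambda: {
        "alpha": ("T1", "T2"),
        "beta": ("T1fs", "FLAIR"),
    })
    n_subjects: int = 10                # per dataset
    size: int = 64
    organ: str = "brain"
    zero_shot_domain: str = "T2fs"

    def validate(self) -> "CorpusConfig":
        if len(self.datasets) < 2:
            raise ValueError("need at least two datasets")
        all_domains = [d for doms in self.datasets.values() for d in doms]
        unknown = set(all_domains) - set(DEFAULT_DOMAINS)
        if unknown:
            raise ValueError(f"unknown domains {sorted(unknown)}")
        if self.zero_shot_domain in all_domains:
            raise ValueError("zero-shot domain must not appear in any dataset")
        return self


@dataclass
class _Subject:
    dataset: str
    subject_key: str
    structure: SubjectStructure
    split: str                           # train | val | test


class SyntheticCorpus:
    """In-memory corpus: subjects with shared structures, renderable domains.

    Subjects are split 3:1:1 into train/validation/test cohorts.
    """

    def __init__(self, config: CorpusConfig, seed: int):
        self.config = config.validate()
        self.seed = seed
        self._clean_cache: dict[tuple[str, str], np.ndarray] = {}
        rng = np.random.default_rng(seed)
        self.subjects: list[_Subject] = []
        for d_idx, (dataset, _domains) in enumerate(sorted(config.datasets.items())):
            for s_idx in range(config.n_subjects):
                frac = s_idx / config.n_subjects
                split = "train" if frac < 0.6 else ("val" if frac < 0.8 else "test")
                structure = generate_structure(
                    int(rng.integers(2**31)), size=config.size)
                self.subjects.append(_Subject(
                    dataset=dataset, subject_key=f"{dataset}-s{s_idx:02d}",
                    structure=structure, split=split))

    # -- access --------------------------------------------------------
    def cohort(self, split: str) -> list[_Subject]:
        return [s for s in self.subjects if s.split == split]

    def domains_of(self, dataset: str) -> tuple[str, ...]:
        return tuple(self.config.datasets[dataset])

    def seen_domains(self) -> list[str]:
        seen = []
        for doms in sorted(self.config.datasets.items()):
            for d in doms[1]:
                if d not in seen:
                    seen.append(d)
        return seen

    def render_volume(self, subject: _Subject, domain_name: str,
                      rng: np.random.Generator) -> VolumeRecord:
        spec = DEFAULT_DOMAINS[domain_name]
        voxels = render_domain(subject.structure, spec, rng)
        return VolumeRecord(
            voxels=voxels, spacing=(1.0, 1.0, 1.0), modality="MRI",
            organ=self.config.organ, keywords=spec.keywords,
            subject_key=subject.subject_key, dataset_key=subject.dataset,
            pairing_key=f"{subject.subject_key}/{domain_name}")

    def paired_slices(self, subject: _Subject, domain_names: Sequence[str],
                      rng: np.random.Generator, center: bool = False,
                      min_foreground: float = 0.1,
                      max_attempts: int = 25) -> list[SliceSample]:
        """Aligned slices of one subject rendered in several domains.

        Slice positions with less than ``min_foreground`` tissue fraction are
        rejected and redrawn, so training/evaluation slices carry anatomy.
        """
        volumes = [self._clean_volume(subject, d) for d in domain_names]
        for _ in range(max_attempts):
            samples = sample_paired_slices(volumes, rng, size=self.config.size,
                                           center=center)
            if center or (samples[0].image > 0).mean() >= min_foreground:
                break
        for name, sample in zip(domain_names, samples):
            sigma = dict(DEFAULT_DOMAINS[name].ops).get("noise", 0.0)
            if sigma:
                body = sample.image > 0
                noisy = sample.image.copy()
                noisy[body] += rng.normal(0.0, float(sigma), size=int(body.sum()))
                sample.image = np.clip(noisy, 0.0, 1.0)
        return samples

    def _clean_volume(self, subject: _Subject, domain_name: str) -> VolumeRecord:
        """Noise-free rendering, cached per (subject, domain); the iid noise
        is drawn per extracted slice instead."""
        key = (subject.subject_key, domain_name)
        if key not in self._clean_cache:
            spec = DEFAULT_DOMAINS[domain_name]
            self._clean_cache[key] = render_domain(subject.structure, spec,
                                                   skip_noise=True)
        spec = DEFAULT_DOMAINS[domain_name]
        return VolumeRecord(
            voxels=self._clean_cache[key], spacing=(1.0, 1.0, 1.0),
            modality="MRI", organ=self.config.organ, keywords=spec.keywords,
            subject_key=subject.subject_key, dataset_key=subject.dataset,
            pairing_key=f"{subject.subject_key}/{domain_name}")

    def slice_corpus(self, split: str, slices_per_subject: int,
                     rng: np.random.Generator) -> list[tuple[np.ndarray, object, str]]:
        """Flat (image, prompt, domain_name) triples for contrastive training."""
        out = []
        for subject in self.cohort(split):
            for _ in range(slices_per_subject):
                domains = self.domains_of(subject.dataset)
                samples = self.paired_slices(subject, domains, rng)
                for name, sample in zip(domains, samples):
                    out.append((sample.image, sample.prompt, name))
        return out


def build_corpus(config: CorpusConfig | None = None, seed: int = 0) -> SyntheticCorpus:
    return SyntheticCorpus(config or CorpusConfig(), seed)


def write_corpus(corpus: SyntheticCorpus, out_dir) -> Path:
    """Write NIfTI volumes, keyword sidecars, and a manifest CSV."""
    import csv

    out_dir = Path(out_dir)
    (out_dir / "volumes").mkdir(parents=True, exist_ok=True)
    (out_dir / "sidecars").mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(corpus.seed + 1)
    rows = []
    for subject in corpus.subjects:
        for domain_name in corpus.domains_of(subject.dataset):
            record = corpus.render_volume(subject, domain_name, rng)
            stem = f"{subject.subject_key}_{domain_name}"
            vol_path = f"volumes/{stem}.nii.gz"
            sidecar_path = f"sidecars/{stem}.json"
            write_nifti(record, out_dir / vol_path)
            sidecar = {"Organ": record.keywords.organ, "Modality": "MR",
                       "Plane": "axial"}
            if record.keywords.sequence:
                sidecar["Sequence"] = record.keywords.sequence
            if record.keywords.preprocess:
                sidecar["Preprocess"] = record.keywords.preprocess
            if record.keywords.contrast:
                sidecar["Contrast"] = record.keywords.contrast
            if record.keywords.manufacturer:
                sidecar["Manufacturer"] = record.keywords.manufacturer
            (out_dir / sidecar_path).write_text(json.dumps(sidecar, indent=2))
            rows.append({
                "path": vol_path, "organ": record.organ, "modality": "MRI",
                "subject": subject.subject_key, "dataset": subject.dataset,
                "pairing_key": record.pairing_key, "split": subject.split,
                "domain": domain_name, "sidecar": sidecar_path,
            })
    manifest = out_dir / "manifest.csv"
    with manifest.open("w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(rows[0].keys()))
        writer.writeheader()
        writer.writerows(rows)
    return manifest
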