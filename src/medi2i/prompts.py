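"""Medical prompts: templated natural-language descriptions of imaging domains.

A scan's metadata (DICOM tags plus curated keyword overrides) is turned into
an ordered list of sentences.  Sentences that strongly determine appearance
(sequence/modality/organ, contrast agent, preprocessing) are flagged
*essential*; the rest (scanner hardware, acquisition parameters, ...) are
optional and may be dropped during training-time augmentation.  Prompt/image
matching for the contrastive label matrix is a sentence-subset rule: a
candidate prompt matches an image when every candidate sentence occurs in the
image's original prompt and every essential sentence of the original survives
in the candidate.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, fields
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "KeywordSet", "MedicalPrompt", "MissingEssentialKeyword",
    "extract_keywords", "render_prompt", "augment_prompt",
    "match_prompts", "build_match_matrix",
    "load_normalization_table", "keywords_from_dicom",
]


class MissingEssentialKeyword(ValueError):
    """Raised when organ, modality, or plane cannot be determined."""


def load_normalization_table() -> dict:
    """Keyword normalization table (units, ordinal words), shipped versioned."""
    with resources.files("medi2i.data").joinpath("normalization.json").open() as fh:
        return json.load(fh)


_TABLE = load_normalization_table()

# DICOM keyword -> KeywordSet field
_DICOM_FIELDS = {
    "Manufacturer": "manufacturer",
    "ManufacturerModelName": "manufacturer_model_name",
    "MagneticFieldStrength": "magnetic_field_strength",
    "ScanningSequence": "scanning_sequence",
    "SequenceVariant": "sequence_variant",
    "ScanOptions": "scan_options",
    "FlipAngle": "flip_angle",
    "EchoTime": "echo_time",
    "RepetitionTime": "repetition_time",
    "InversionTime": "inversion_time",
    "Modality": "modality",
    "BodyPartExamined": "organ",
}

# curated override keys (sidecar JSON) -> KeywordSet field
_OVERRIDE_FIELDS = {
    **_DICOM_FIELDS,
    "Organ": "organ",
    "Sequence": "sequence",
    "SequenceFrameNumber": "sequence_frame_number",
    "Contrast": "contrast",
    "Preprocess": "preprocess",
    "Plane": "plane",
}


@dataclass
class KeywordSet:
    """Normalized tokens describing one scan; organ/modality/plane required."""

    organ: str = ""
    modality: str = ""
    plane: str = ""
    sequence: str | None = None
    sequence_frame_number: str | None = None
    contrast: str | None = None
    preprocess: str | None = None
    manufacturer: str | None = None
    manufacturer_model_name: str | None = None
    magnetic_field_strength: str | None = None
    scanning_sequence: str | None = None
    sequence_variant: str | None = None
    scan_options: str | None = None
    flip_angle: str | None = None
    echo_time: str | None = None
    repetition_time: str | None = None
    inversion_time: str | None = None

    def validate(self) -> "KeywordSet":
        for name in ("organ", "modality", "plane"):
            if not getattr(self, name):
                raise MissingEssentialKeyword(f"essential keyword missing: {name}")
        return self

    def as_dict(self) -> dict[str, str]:
        return {f.name: getattr(self, f.name) for f in fields(self)
                if getattr(self, f.name) is not None and getattr(self, f.name) != ""}


_WS = re.compile(r"\s+")


def _normalize_text(s: str) -> str:
    return _WS.sub(" ", s).strip()


@dataclass(frozen=True)
class MedicalPrompt:
    """Ordered (sentence, essential) pairs; the textual identity of a domain."""

    sentences: tuple[tuple[str, bool], ...]
    subject_key: str = ""
    domain_key: str = ""

    def __post_init__(self):
        cleaned: list[tuple[str, bool]] = []
        seen: set[str] = set()
        for text, essential in self.sentences:
            text = _normalize_text(text)
            if not text:
                raise ValueError("prompt sentences must be non-empty")
            if text in seen:
                continue
            seen.add(text)
            cleaned.append((text, bool(essential)))
        if not any(e for _, e in cleaned):
            raise ValueError("a prompt needs at least one essential sentence")
        object.__setattr__(self, "sentences", tuple(cleaned))

    def texts(self) -> tuple[str, ...]:
        return tuple(t for t, _ in self.sentences)

    def essential_texts(self) -> frozenset[str]:
        return frozenset(t for t, e in self.sentences if e)

    def text(self) -> str:
        return " ".join(self.texts())

    # -- plain-text serialization: one sentence per line, "!" = essential --
    def to_text(self) -> str:
        return "\n".join(("!" if e else "") + t for t, e in self.sentences)

    @classmethod
    def from_text(cls, blob: str, subject_key: str = "", domain_key: str = "") -> "MedicalPrompt":
        sentences = []
        for line in blob.splitlines():
            line = line.strip()
            if not line:
                continue
            essential = line.startswith("!")
            sentences.append((line.lstrip("!"), essential))
        return cls(tuple(sentences), subject_key=subject_key, domain_key=domain_key)

    def save(self, path) -> None:
        Path(path).write_text(self.to_text() + "\n", encoding="utf-8")

    @classmethod
    def load(cls, path, **kw) -> "MedicalPrompt":
        return cls.from_text(Path(path).read_text(encoding="utf-8"), **kw)


def _format_value(value) -> str:
    if isinstance(value, str):
        return _normalize_text(value)
    if isinstance(value, (list, tuple)):
        return ", ".join(_format_value(v) for v in value)
    if isinstance(value, (int, np.integer)):
        return str(int(value))
    if isinstance(value, (float, np.floating)):
        v = float(value)
        return f"{v:.1f}" if v == int(v) else f"{v:g}"
    return str(value)


def extract_keywords(tags: Mapping[str, object],
                     overrides: Mapping[str, object] | None = None) -> KeywordSet:
    """Merge DICOM-style tags with curated overrides into a KeywordSet.

    Overrides win over tags; unknown keys are ignored; organ/modality/plane
    must be present after merging.
    """
    values: dict[str, str] = {}
    for source, mapping in ((tags, _DICOM_FIELDS), (overrides or {}, _OVERRIDE_FIELDS)):
        for key, value in source.items():
            field_name = mapping.get(key)
            if field_name is None or value is None or value == "":
                continue
            text = _format_value(value)
            if field_name == "modality":
                text = _TABLE["modality_names"].get(text.upper(), text)
            if field_name in _TABLE["lowercase_fields"]:
                text = text.lower()
            values[field_name] = text
    return KeywordSet(**values).validate()


def keywords_from_dicom(path, overrides: Mapping[str, object] | None = None) -> KeywordSet:
    """Read a DICOM file's header and extract keywords from it."""
    import pydicom

    ds = pydicom.dcmread(str(path), stop_before_pixels=True)
    tags = {key: ds.get(key) for key in _DICOM_FIELDS if key in ds}
    return extract_keywords(tags, overrides)


def _scanner_sentence(k: KeywordSet) -> str | None:
    parts = [p for p in (k.manufacturer, k.manufacturer_model_name) if p]
    if k.magnetic_field_strength:
        parts.append(f"{k.magnetic_field_strength} {_TABLE['units']['magnetic_field_strength']}")
    if not parts:
        return None
    return f"The scan is acquired on the {' '.join(parts)} scanner."


def _acquisition_sentence(k: KeywordSet) -> str | None:
    clauses = []
    if k.flip_angle:
        clauses.append(f"a {k.flip_angle} {_TABLE['units']['flip_angle']} flip angle")
    if k.echo_time:
        clauses.append(f"an echo time of {k.echo_time} {_TABLE['units']['echo_time']}")
    if k.repetition_time:
        clauses.append(f"a repetition time of {k.repetition_time} {_TABLE['units']['repetition_time']}")
    if k.inversion_time:
        clauses.append(f"an inversion time of {k.inversion_time} {_TABLE['units']['inversion_time']}")
    if not clauses:
        return None
    return f"The image is acquired using {', '.join(clauses)}."


def render_prompt(keywords: KeywordSet, subject_key: str = "",
                  domain_key: str = "") -> MedicalPrompt:
    """Render the sentence template for one scan.

    Sentences whose keywords are all absent are omitted; the domain sentence
    (sequence/modality/organ, with the time-point rendered inside it) plus the
    contrast and preprocessing sentences are essential.
    """
    k = keywords.validate()
    lead = "A"
    descriptors = " ".join(p for p in (k.sequence_frame_number, k.sequence) if p)
    if descriptors:
        first = f"{lead} {descriptors} {k.modality} of the {k.organ} for the subject."
    else:
        first = f"{lead} {k.modality} of the {k.organ} for the subject."

    sentences: list[tuple[str, bool]] = [(first, True)]
    if k.contrast:
        sentences.append((
            f"The subject undergoes the contrast-enhanced scan with the {k.contrast} agent.",
            True))
    if (s := _scanner_sentence(k)) is not None:
        sentences.append((s, False))
    if k.scanning_sequence:
        sentences.append((f"The scanning sequences consist of {k.scanning_sequence}.", False))
    if k.sequence_variant:
        sentences.append((f"The sequence variants consist of {k.sequence_variant}.", False))
    if k.scan_options:
        sentences.append((f"The scan options consist of {k.scan_options}.", False))
    if (s := _acquisition_sentence(k)) is not None:
        sentences.append((s, False))
    if k.preprocess:
        sentences.append((f"The image preprocessing consists of {k.preprocess}.", True))
    sentences.append((f"The image is visualized in the {k.plane} plane.", False))
    return MedicalPrompt(tuple(sentences), subject_key=subject_key, domain_key=domain_key)


def augment_prompt(prompt: MedicalPrompt, rng: np.random.Generator,
                   drop_prob: float = 0.5, keep_first: bool = False) -> MedicalPrompt:
    """Randomly delete optional sentences and shuffle the survivors.

    Essential sentences are always retained.  ``keep_first`` pins the leading
    sentence to its position during the shuffle.
    """
    if not 0.0 <= drop_prob <= 1.0:
        raise ValueError("drop_prob must lie in [0, 1]")
    kept = [(t, e) for t, e in prompt.sentences
            if e or rng.random() >= drop_prob]
    if keep_first and prompt.sentences and kept and kept[0] == prompt.sentences[0]:
        head, tail = kept[:1], kept[1:]
    else:
        head, tail = [], kept
    order = rng.permutation(len(tail))
    shuffled = head + [tail[i] for i in order]
    return MedicalPrompt(tuple(shuffled), subject_key=prompt.subject_key,
                         domain_key=prompt.domain_key)


def match_prompts(original: MedicalPrompt, candidate: MedicalPrompt) -> bool:
    """Sentence-subset matching rule.

    True iff every candidate sentence appears in the original prompt and every
    essential sentence of the original appears in the candidate.
    """
    orig_texts = set(original.texts())
    cand_texts = set(candidate.texts())
    return cand_texts <= orig_texts and original.essential_texts() <= cand_texts


def build_match_matrix(image_prompts: Sequence[MedicalPrompt],
                       text_prompts: Sequence[MedicalPrompt]) -> np.ndarray:
    """Binary label matrix M: rows = text prompts, columns = images.

    ``M[i, j] = 1`` when text prompt ``i`` matches the original prompt of
    image ``j``; one prompt may match several images.
    """
    if not image_prompts or not text_prompts:
        raise ValueError("prompt lists must be non-empty")
    m = np.zeros((len(text_prompts), len(image_prompts)), dtype=np.int8)
    for i, cand in enumerate(text_prompts):
        for j, orig in enumerate(image_prompts):
            m[i, j] = match_prompts(original=orig, candidate=cand)
    return m
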