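"""Lower-cased byte-pair-encoding tokenizer for medical prompts.

The text encoder consumes BPE token ids wrapped in [SOS]/[EOS].  For desk use
the vocabulary is trained deterministically from the prompt-template lexicon
and shipped as JSON; a full-scale vocabulary trained on a real prompt corpus
is loadable through the same class.
"""

from __future__ import annotations

import hashlib
import json
import re
from collections import Counter
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

__all__ = ["BPETokenizer", "train_bpe", "template_lexicon", "load_default_tokenizer"]

SOS, EOS, PAD, UNK = "[SOS]", "[EOS]", "[PAD]", "[UNK]"
_SPECIALS = (PAD, SOS, EOS, UNK)
_EOW = "</w>"
_WORD_RE = re.compile(r"\d+\.\d+|\w+|[^\w\s]")


def _words(text: str) -> list[str]:
    return _WORD_RE.findall(text.lower())


class BPETokenizer:
    def __init__(self, vocab: Sequence[str], merges: Sequence[tuple[str, str]]):
        self.vocab = list(vocab)
        self.merges = [tuple(m) for m in merges]
        self.token_to_id = {t: i for i, t in enumerate(self.vocab)}
        self._ranks = {m: i for i, m in enumerate(self.merges)}
        self._cache: dict[str, list[str]] = {}

    # -- core BPE ------------------------------------------------------
    def _bpe(self, word: str) -> list[str]:
        if word in self._cache:
            return self._cache[word]
        symbols = list(word[:-len(_EOW)]) + [_EOW] if word.endswith(_EOW) else list(word)
        while len(symbols) > 1:
            pairs = [(self._ranks.get((a, b), 1 << 30), i)
                     for i, (a, b) in enumerate(zip(symbols, symbols[1:]))]
            rank, i = min(pairs)
            if rank == 1 << 30:
                break
            symbols = symbols[:i] + [symbols[i] + symbols[i + 1]] + symbols[i + 2:]
        self._cache[word] = symbols
        return symbols

    def encode(self, text: str, add_special: bool = True) -> list[int]:
        unk = self.token_to_id[UNK]
        ids: list[int] = [self.token_to_id[SOS]] if add_special else []
        for word in _words(text):
            for tok in self._bpe(word + _EOW):
                ids.append(self.token_to_id.get(tok, unk))
        if add_special:
            ids.append(self.token_to_id[EOS])
        return ids

    def decode(self, ids: Iterable[int]) -> str:
        toks = [self.vocab[i] for i in ids if self.vocab[i] not in _SPECIALS]
        return "".join(toks).replace(_EOW, " ").strip()

    # -- bookkeeping ---------------------------------------------------
    @property
    def vocab_size(self) -> int:
        return len(self.vocab)

    @property
    def sos_id(self) -> int:
        return self.token_to_id[SOS]

    @property
    def eos_id(self) -> int:
        return self.token_to_id[EOS]

    @property
    def pad_id(self) -> int:
        return self.token_to_id[PAD]

    def vocab_hash(self) -> str:
        blob = json.dumps({"vocab": self.vocab, "merges": self.merges}).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(
            {"vocab": self.vocab, "merges": [list(m) for m in self.merges]},
            indent=0), encoding="utf-8")

    @classmethod
    def load(cls, path) -> "BPETokenizer":
        blob = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(blob["vocab"], [tuple(m) for m in blob["merges"]])


def train_bpe(corpus: Iterable[str], n_merges: int = 384) -> BPETokenizer:
    """Train BPE merges on lower-cased text, deterministically.

    Ties between pair counts are broken lexicographically so the same corpus
    always yields the same merge table.
    """
    word_freq = Counter()
    for text in corpus:
        for w in _words(text):
            word_freq[w + _EOW] += 1
    splits = {w: list(w[:-len(_EOW)]) + [_EOW] for w in word_freq}
    alphabet = sorted({s for parts in splits.values() for s in parts})
    merges: list[tuple[str, str]] = []
    for _ in range(n_merges):
        pair_counts: Counter = Counter()
        for w, parts in splits.items():
            f = word_freq[w]
            for pair in zip(parts, parts[1:]):
                pair_counts[pair] += f
        if not pair_counts:
            break
        best = max(pair_counts.items(), key=lambda kv: (kv[1], tuple(map(str, kv[0]))))
        if best[1] < 2:
            break
        a, b = best[0]
        merges.append((a, b))
        merged = a + b
        for w, parts in splits.items():
            i = 0
            while i < len(parts) - 1:
                if parts[i] == a and parts[i + 1] == b:
                    parts[i:i + 2] = [merged]
                else:
                    i += 1
    tokens = sorted({s for parts in splits.values() for s in parts} | set(alphabet))
    vocab = list(_SPECIALS) + tokens
    return BPETokenizer(vocab, merges)


def template_lexicon() -> list[str]:
    """Representative prompt sentences covering the template token slots."""
    from .prompts import KeywordSet, render_prompt

    organs = ["brain", "breast", "abdomen", "pelvis"]
    modalities = ["magnetic resonance imaging", "computed tomography",
                  "cone beam computed tomography"]
    sequences = [None, "T1-weighted", "T2-weighted", "T2 star-weighted",
                 "T2-weighted-fluid-attenuated inversion recovery", "DCE",
                 "susceptibility weighted imaging", "FLAIR"]
    planes = ["axial", "coronal", "sagittal"]
    frames = [None, "first", "second", "third", "fourth", "fifth", "sixth"]
    sentences: list[str] = []
    for organ in organs:
        for modality in modalities:
            for sequence in sequences:
                p = render_prompt(KeywordSet(
                    organ=organ, modality=modality, plane=planes[0],
                    sequence=sequence))
                sentences.append(p.text())
    for frame in frames[1:]:
        p = render_prompt(KeywordSet(
            organ="breast", modality="magnetic resonance imaging",
            plane="axial", sequence="DCE", sequence_frame_number=frame,
            contrast="Gadolinium"))
        sentences.append(p.text())
    for plane in planes:
        sentences.append(f"The image is visualized in the {plane} plane.")
    extras = [
        "The subject undergoes the contrast-enhanced scan with the Gadolinium agent.",
        "The scan is acquired on the Philips Ingenia 3.0 Tesla scanner.",
        "The scan is acquired on the Siemens Prisma 1.5 Tesla scanner.",
        "The scan is acquired on the GE Signa 3.0 Tesla scanner.",
        "The scanning sequences consist of GR, SE, IR, EP.",
        "The sequence variants consist of SK, SP, OSP, MP.",
        "The scan options consist of FS, PFP, SAT1.",
        "The image is acquired using a 9 degree flip angle, an echo time of 4.6 ms, "
        "a repetition time of 9.8 ms, an inversion time of 900 ms.",
        "The image preprocessing consists of skull removal.",
        "The image preprocessing consists of fat saturation.",
        "0 1 2 3 4 5 6 7 8 9 10 90 150 1024 3000",
    ]
    sentences.extend(extras)
    return sentences


def load_default_tokenizer() -> BPETokenizer:
    """The shipped vocabulary trained from the template lexicon."""
    path = resources.files("medi2i.data").joinpath("vocab_bpe.json")
    with path.open() as fh:
        blob = json.load(fh)
    return BPETokenizer(blob["vocab"], [tuple(m) for m in blob["merges"]])
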