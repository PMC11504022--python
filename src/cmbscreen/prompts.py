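"""Clinical text prompts for candidate classification and their vector encodings.

Each candidate microbleed region is described by a short ordered list of
statements — patient demographics, candidate geometry, and the detection
status of the neighbouring slices — mirroring the "asking" step of the
clinical workflow.  Statements are encoded into fixed 768-wide vectors by a
pluggable sentence encoder; the built-in encoder is a deterministic,
network-free feature-hashing encoder so the whole pipeline runs offline.
A pretrained sentence encoder (e.g. a BERT-family model) can be supplied as
any callable mapping a string to a 768-vector.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .boxes import Box

__all__ = ["PatientMeta", "PromptSet", "TextEmbedding", "build_prompts",
           "encode_prompts", "HashingEncoder", "EMBED_DIM"]

EMBED_DIM = 768

_GENDERS = ("male", "female")


@dataclass(frozen=True)
class PatientMeta:
    patient_id: str
    gender: str
    age: int
    history: tuple[str, ...] = ()
    lifestyle: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.gender not in _GENDERS:
            raise ValueError(f"gender must be one of {_GENDERS}, got {self.gender!r}")
        if not (0 <= int(self.age) <= 130):
            raise ValueError(f"age out of range: {self.age}")


@dataclass(frozen=True)
class PromptSet:
    statements: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.statements or any(not s for s in self.statements):
            raise ValueError("prompt set must be a non-empty list of non-empty strings")

    def __len__(self) -> int:
        return len(self.statements)


@dataclass(frozen=True)
class TextEmbedding:
    matrix: np.ndarray  # (768, n)
    encoder_name: str

    def __post_init__(self) -> None:
        if self.matrix.shape[0] != EMBED_DIM:
            raise ValueError(f"embedding width must be {EMBED_DIM}, got {self.matrix.shape[0]}")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("embedding contains non-finite entries")


def _yesno(flag: bool) -> str:
    return "yes" if flag else "no"


def build_prompts(meta: PatientMeta, box: Box, prev_hit: bool, next_hit: bool) -> PromptSet:
    """Instantiate the prompt templates for one candidate.

    Statement order is fixed: demographics, geometry, previous-slice adjacency,
    next-slice adjacency, then one statement per optional history/lifestyle item.
    "Length" maps to box height and "width" to box width, both rounded half-up
    to integer pixels.
    """
    length = int(np.floor(box.height + 0.5))
    width = int(np.floor(box.width + 0.5))
    statements = [
        f"This is a {meta.gender} patient with {int(meta.age)} years old.",
        f"Target length and width are {length} and {width} pixels.",
        f"The detection status of the previous frame at the same position is {_yesno(prev_hit)}.",
        f"The detection status of the next frame at the same position is {_yesno(next_hit)}.",
    ]
    for item in meta.history:
        statements.append(f"The patient has a history of {item}.")
    for item in meta.lifestyle:
        statements.append(f"The patient has a habit of {item}.")
    return PromptSet(tuple(statements))


class HashingEncoder:
    """Deterministic feature-hashing sentence encoder.

    Tokenizes into lowercase words plus character bigrams (so numeric tokens
    like ages contribute digit-level features), hashes each token into the
    768-dim space with a signed hash, and L2-normalizes.  Stable across runs
    and platforms for a fixed seed: hashing uses blake2b, not Python's
    randomized ``hash``.
    """

    name = "feature-hashing-768"

    def __init__(self, seed: int = 0, dim: int = EMBED_DIM) -> None:
        self.seed = int(seed)
        self.dim = dim

    def _tokens(self, text: str) -> list[str]:
        words = re.findall(r"[a-z0-9]+", text.lower())
        toks = list(words)
        for w in words:
            toks.extend(f"#{w[i:i + 2]}" for i in range(len(w) - 1))
        return toks

    def __call__(self, text: str) -> np.ndarray:
        vec = np.zeros(self.dim, dtype=np.float64)
        for tok in self._tokens(text):
            h = hashlib.blake2b(f"{self.seed}:{tok}".encode(), digest_size=8).digest()
            val = int.from_bytes(h, "big")
            idx = val % self.dim
            sign = 1.0 if (val >> 32) & 1 else -1.0
            vec[idx] += sign
        norm = np.linalg.norm(vec)
        return vec / norm if norm > 0 else vec


def encode_prompts(p: PromptSet, encoder: Callable[[str], np.ndarray] | None = None) -> TextEmbedding:
    """Encode each statement to a 768-vector; column i encodes statement i."""
    if encoder is None:
        encoder = HashingEncoder()
    cols = []
    for s in p.statements:
        v = np.asarray(encoder(s), dtype=np.float64).reshape(-1)
        if v.shape[0] != EMBED_DIM:
            raise ValueError(f"encoder produced width {v.shape[0]}, expected {EMBED_DIM}")
        cols.append(v)
    name = getattr(encoder, "name", type(encoder).__name__)
    return TextEmbedding(np.stack(cols, axis=1), name)


def prompts_to_json(p: PromptSet) -> list[str]:
    return list(p.statements)
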