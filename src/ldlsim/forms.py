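"""Orthographic form coding: letter-trigram cue vectors and neighbourhoods.

Word forms are represented as binary vectors over boundary-padded letter
trigrams: ``aback`` -> ``#ab, aba, bac, ack, ck#``.  The cue matrix ``C``
stacks one such row vector per word form and is the input side of the
comprehension mapping and the output side of the production mapping.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import edlib
import numpy as np
import pandas as pd

BOUNDARY = "#"


class InvalidWordformError(ValueError):
    """Raised for empty or non-letter stimulus strings."""


def validate_wordform(word: str) -> str:
    """Lower-case and validate a stimulus string.

    Only alphabetic strings are accepted; the boundary marker ``#`` is
    reserved for padding and may not occur inside a word form.
    """
    if not isinstance(word, str) or len(word) == 0:
        raise InvalidWordformError(f"empty or non-string wordform: {word!r}")
    w = word.lower()
    if not w.isalpha():
        raise InvalidWordformError(f"wordform must be letters only: {word!r}")
    return w


def extract_trigrams(word: str) -> list[str]:
    """Unique letter trigrams of the boundary-padded word, in first-occurrence order.

    The word is padded once with ``#`` at each end, all length-3 windows are
    taken, and duplicates are collapsed keeping the first occurrence.  Words
    shorter than three letters still yield at least one trigram (a
    single-letter word ``x`` yields ``#x#``).
    """
    w = validate_wordform(word)
    padded = BOUNDARY + w + BOUNDARY
    seen: dict[str, None] = {}
    for i in range(len(padded) - 2):
        seen.setdefault(padded[i : i + 2 + 1], None)
    return list(seen)


@dataclass(frozen=True)
class TrigramIndex:
    """Bijective mapping between trigrams and cue-matrix columns."""

    trigrams: tuple[str, ...]
    _pos: dict[str, int] = field(repr=False, compare=False, default_factory=dict)

    def __post_init__(self) -> None:
        pos = {t: i for i, t in enumerate(self.trigrams)}
        if len(pos) != len(self.trigrams):
            raise ValueError("duplicate trigrams in index")
        object.__setattr__(self, "_pos", pos)

    def __len__(self) -> int:
        return len(self.trigrams)

    def __getitem__(self, trigram: str) -> int:
        return self._pos[trigram]

    def __contains__(self, trigram: str) -> bool:
        return trigram in self._pos

    def columns(self, trigrams: Iterable[str]) -> np.ndarray:
        """Column indices for a collection of trigrams (raises on unknown)."""
        try:
            return np.array([self._pos[t] for t in trigrams], dtype=np.intp)
        except KeyError as exc:
            raise KeyError(
                f"trigram {exc.args[0]!r} not in index; build the index over all stimuli up front"
            ) from exc

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"trigram": self.trigrams, "column": np.arange(len(self))})

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "TrigramIndex":
        ordered = frame.sort_values("column")["trigram"].tolist()
        return cls(tuple(ordered))


def build_trigram_index(words: Sequence[str]) -> TrigramIndex:
    """Index over the union of trigrams of all words, in scan order."""
    if len(words) == 0:
        raise ValueError("empty word list")
    seen: dict[str, None] = {}
    for w in words:
        for t in extract_trigrams(w):
            seen.setdefault(t, None)
    return TrigramIndex(tuple(seen))


def encode_cue_vector(word: str, index: TrigramIndex) -> np.ndarray:
    """Binary cue row vector ``c`` for a single word form."""
    c = np.zeros(len(index), dtype=np.float64)
    c[index.columns(extract_trigrams(word))] = 1.0
    return c


def build_cue_matrix(
    words: Sequence[str], index: TrigramIndex | None = None
) -> tuple[np.ndarray, TrigramIndex]:
    """Cue matrix ``C`` (words x trigrams) and its trigram index.

    Row *i* has ones exactly at the columns of ``extract_trigrams(words[i])``.
    If ``index`` is given it must cover every trigram of ``words``.
    """
    if len(words) == 0:
        raise ValueError("empty word list")
    if index is None:
        index = build_trigram_index(words)
    C = np.zeros((len(words), len(index)), dtype=np.float64)
    for i, w in enumerate(words):
        C[i, index.columns(extract_trigrams(w))] = 1.0
    return C, index


def coltheart_neighbours(word: str, lexicon: Iterable[str]) -> set[str]:
    """Same-length lexicon members differing in exactly one letter position.

    The word itself is excluded even when present in the lexicon.
    """
    w = validate_wordform(word)
    out: set[str] = set()
    for cand in lexicon:
        c = cand.lower()
        if c == w or len(c) != len(w):
            continue
        if sum(a != b for a, b in zip(w, c)) == 1:
            out.add(cand)
    return out


def levenshtein_neighbourhood_size(word: str, lexicon: Iterable[str]) -> int:
    """Number of lexicon members at edit distance exactly 1 from the word.

    Substitutions, insertions and deletions all count; identical strings
    (distance 0) do not.
    """
    w = validate_wordform(word)
    n = 0
    for cand in lexicon:
        c = cand.lower()
        if c == w or abs(len(c) - len(w)) > 1:
            continue
        if edlib.align(w, c, task="distance", k=1)["editDistance"] == 1:
            n += 1
    return n
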