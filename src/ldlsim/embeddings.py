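"""Loading and summarising word embeddings.

Embeddings are an *input* to the simulation: each word in the lexicon needs a
fixed real-valued semantic vector (a row of the semantic matrix ``S``).  The
on-disk format is the plain-text convention used by GloVe/word2vec: one token
followed by ``d`` numbers per line, with an optional ``count dim`` header.

Vectors are deliberately NOT re-normalised on load: cosine-based measures
normalise internally, while the L1-norm measure must see raw predicted
values.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)


class MissingEmbeddingError(KeyError):
    """Raised when requested words have no embedding in the file."""

    def __init__(self, missing: list[str]):
        self.missing = missing
        super().__init__(f"no embedding for {len(missing)} word(s): {missing[:10]}")


class EmbeddingFormatError(ValueError):
    """Raised for ragged or otherwise malformed embedding files."""


def _looks_like_header(parts: list[str]) -> bool:
    if len(parts) != 2:
        return False
    try:
        int(parts[0]), int(parts[1])
    except ValueError:
        return False
    return True


def read_embedding_file(path) -> dict[str, np.ndarray]:
    """Parse a text embedding file into a token -> vector dict.

    The first occurrence of a duplicated token wins (a warning is logged).
    All vectors must share one dimensionality, inferred from the first data
    line; a two-integer first line is treated as a ``count dim`` header.
    """
    vectors: dict[str, np.ndarray] = {}
    dim: int | None = None
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.rstrip("\n").split(" ")
            if not parts or parts == [""]:
                continue
            if lineno == 1 and _looks_like_header(parts):
                dim = int(parts[1])
                continue
            token, values = parts[0], parts[1:]
            if dim is None:
                dim = len(values)
            if len(values) != dim:
                raise EmbeddingFormatError(
                    f"line {lineno}: expected {dim} values, got {len(values)}"
                )
            if token in vectors:
                logger.warning("duplicate token %r at line %d ignored", token, lineno)
                continue
            vectors[token] = np.asarray(values, dtype=np.float64)
    if not vectors:
        raise EmbeddingFormatError(f"no embeddings found in {path}")
    return vectors


def load_embeddings(path, wordlist: Sequence[str]) -> np.ndarray:
    """Semantic matrix ``S`` with rows aligned to ``wordlist`` order."""
    vectors = read_embedding_file(path)
    missing = [w for w in wordlist if w not in vectors]
    if missing:
        raise MissingEmbeddingError(missing)
    return np.stack([vectors[w] for w in wordlist])


def write_embeddings(path, words: Sequence[str], S: np.ndarray) -> None:
    """Write a semantic matrix in the same text format ``load_embeddings`` reads."""
    S = np.asarray(S)
    with open(path, "w", encoding="utf-8") as fh:
        for w, row in zip(words, S):
            fh.write(w + " " + " ".join(format(v, ".8g") for v in row) + "\n")


def word_centroid(S: np.ndarray) -> np.ndarray:
    """Mean of all word vectors: the 'wordness' target for nonword stimuli
    that nevertheless received a word response."""
    S = np.asarray(S, dtype=np.float64)
    if S.ndim != 2 or S.shape[0] == 0:
        raise ValueError("semantic matrix must be a non-empty 2-D array")
    return S.mean(axis=0)
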