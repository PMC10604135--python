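"""Word-vector loading and the classifier's embedding weight matrix.

Vector files are plain text, one ``word v1 ... v_d`` line per word
(space-delimited), as distributed for GloVe- and BioWordVec-style
pretrained embeddings. The default dimensionality is 200.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

from ppiminer.types import MASK_FIRST, MASK_SECOND

DEFAULT_DIM = 200
OOV_RANGE = 0.25  # out-of-vocabulary rows drawn uniform(-0.25, 0.25)

__all__ = ["EmbeddingMatrix", "build_embedding_matrix", "build_vocab", "iter_word_vectors"]


@dataclass
class EmbeddingMatrix:
    """Vocabulary index plus a ``|V|+1 x d`` weight matrix.

    Row 0 is the all-zero padding vector; every vocabulary word owns
    exactly one row at index ``vocab[word] >= 1``.
    """

    vocab: dict[str, int]
    matrix: np.ndarray
    dim: int = field(default=DEFAULT_DIM)

    def __post_init__(self) -> None:
        if self.matrix.shape != (len(self.vocab) + 1, self.dim):
            raise ValueError(
                f"matrix shape {self.matrix.shape} != ({len(self.vocab) + 1}, {self.dim})"
            )
        if np.any(self.matrix[0] != 0.0):
            raise ValueError("row 0 is reserved for padding and must be zero")

    def index(self, word: str) -> int:
        """Index of ``word``, or 0 (padding/unknown) if absent."""
        return self.vocab.get(word, 0)


def iter_word_vectors(path: str | Path, dim: int) -> Iterator[tuple[str, np.ndarray]]:
    """Stream ``(word, vector)`` pairs from a plain-text vector file."""
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.rstrip("\n").split(" ")
            if len(parts) < 2:
                continue
            if len(parts) != dim + 1:
                raise ValueError(
                    f"{path}:{lineno}: expected {dim} values for {parts[0]!r}, got {len(parts) - 1}"
                )
            yield parts[0], np.asarray(parts[1:], dtype=np.float64)


def build_vocab(token_sequences: Iterable[Sequence[str]]) -> dict[str, int]:
    """Map each distinct token to an index >= 1, in first-occurrence order.

    The mask tokens ``PROT1``/``PROT2`` are always present so that masked
    training instances and raw inference sentences share one vocabulary.
    """
    vocab: dict[str, int] = {}
    for word in (MASK_FIRST, MASK_SECOND):
        vocab[word] = len(vocab) + 1
    for seq in token_sequences:
        for word in seq:
            if word not in vocab:
                vocab[word] = len(vocab) + 1
    return vocab


def build_embedding_matrix(
    vocab: dict[str, int] | Sequence[str],
    vector_file: str | Path | None,
    dim: int = DEFAULT_DIM,
    seed: int = 0,
) -> EmbeddingMatrix:
    """Assemble the frozen embedding-layer weight matrix for ``vocab``.

    Words found in ``vector_file`` copy their pretrained vector; words
    missing from it (including, typically, PROT1/PROT2) get a seeded
    uniform(-0.25, 0.25) row. Row 0 stays all-zero for padding. With
    ``vector_file=None`` every row is drawn from the OOV distribution.
    """
    if not isinstance(vocab, dict):
        words = list(vocab)
        for word in (MASK_FIRST, MASK_SECOND):
            if word not in words:
                words.append(word)
        vocab = {w: k + 1 for k, w in enumerate(words)}
    else:
        vocab = dict(vocab)
        for word in (MASK_FIRST, MASK_SECOND):
            if word not in vocab:
                vocab[word] = len(vocab) + 1

    rng = np.random.default_rng(seed)
    matrix = np.zeros((len(vocab) + 1, dim))
    # OOV rows are drawn in vocabulary-index order so the result is a pure
    # function of (vocab, file, seed) regardless of file ordering.
    pretrained: dict[int, np.ndarray] = {}
    if vector_file is not None:
        for word, vec in iter_word_vectors(vector_file, dim):
            idx = vocab.get(word)
            if idx is not None:
                pretrained[idx] = vec
    for word, idx in sorted(vocab.items(), key=lambda kv: kv[1]):
        if idx in pretrained:
            matrix[idx] = pretrained[idx]
        else:
            matrix[idx] = rng.uniform(-OOV_RANGE, OOV_RANGE, size=dim)
    return EmbeddingMatrix(vocab=vocab, matrix=matrix, dim=dim)
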