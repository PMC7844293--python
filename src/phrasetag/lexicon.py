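"""Word tokens, grammatical categories and embedding-space similarity.

A lexicon is simply a list of :class:`WordToken`: a word form, its (single,
unambiguous) grammatical category, and a distributional embedding vector in
the style of skipgram/word2vec or fastText.  Stream construction operates
on cosine similarities between these vectors.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import InvalidInputError


class Category(str, enum.Enum):
    """Grammatical categories admitted into the stimulus lexicon."""

    ADJ = "ADJ"
    NOUN = "NOUN"
    VERB = "VERB"
    PRON = "PRON"
    ADV = "ADV"
    DET = "DET"
    PREP = "PREP"


@dataclass(frozen=True)
class WordToken:
    """One lexicon entry: a word form, its category, and its embedding.

    Identity (hashing/equality) is by ``(form, category)``; the embedding is
    carried data.  The embedding must have at least one nonzero component so
    cosine similarities are defined.
    """

    form: str
    category: Category
    embedding: np.ndarray = field(compare=False, repr=False)

    def __post_init__(self):
        if not self.form:
            raise InvalidInputError("word form must be non-empty")
        emb = np.asarray(self.embedding, dtype=float)
        if emb.ndim != 1 or not np.any(emb):
            raise InvalidInputError(
                f"embedding for {self.form!r} must be a 1-d vector with a nonzero component"
            )
        object.__setattr__(self, "embedding", emb)


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine of the angle between two vectors, in [-1, 1].

    Raises
    ------
    InvalidInputError
        If the vectors differ in length or either has zero norm.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape or u.ndim != 1:
        raise InvalidInputError(f"vectors must be 1-d and same length, got {u.shape} and {v.shape}")
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise InvalidInputError("cosine similarity undefined for a zero-norm vector")
    return float(np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0))


def retain_similar_pairs(
    lexicon: Iterable[WordToken],
    cat_a: Category,
    cat_b: Category,
    lo: float = 0.75,
    hi: float = 1.0,
) -> set[tuple[WordToken, WordToken]]:
    """All ordered cross-category pairs whose cosine similarity is in [lo, hi].

    The default window [0.75, 1] is the hand-tuned retention band used when
    chaining adjective-noun (or adjective-verb) pairs into streams; it is a
    parameter, not a constant.  An empty result is returned as-is so callers
    can detect it and relax the window.
    """
    if not lo < hi:
        raise InvalidInputError(f"similarity window requires lo < hi, got [{lo}, {hi}]")
    words_a = [t for t in lexicon if t.category == cat_a]
    words_b = [t for t in lexicon if t.category == cat_b]
    if not words_a or not words_b:
        raise InvalidInputError(f"lexicon has no tokens for {cat_a.value} x {cat_b.value}")
    pairs: set[tuple[WordToken, WordToken]] = set()
    for a in words_a:
        for b in words_b:
            if lo <= cosine_similarity(a.embedding, b.embedding) <= hi:
                pairs.add((a, b))
    return pairs


def embedding_matrix(tokens: Sequence[WordToken]) -> np.ndarray:
    """Stack token embeddings into an (n_tokens, dim) array."""
    dims = {t.embedding.shape[0] for t in tokens}
    if len(dims) > 1:
        raise InvalidInputError(f"tokens mix embedding dimensions: {sorted(dims)}")
    return np.stack([t.embedding for t in tokens])
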