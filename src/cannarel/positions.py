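"""Entity-relative position sequences and position-aware input encoding.

Each token gets a signed offset to each entity span — negative before the
span, zero inside, positive after — clipped to a finite range so it can
index a learned position-embedding table.  The per-token input to the
convolutional encoder is the concatenation of the word embedding and the
two position embeddings (cannabis first, depression second).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from .locator import EntitySpan, MASK_TOKENS

__all__ = [
    "PositionSequence",
    "EmbeddingTables",
    "relative_positions",
    "embed_words",
    "embed_positions",
    "encode",
]

DEFAULT_CLIP = 50
DEFAULT_WORD_DIM = 300
DEFAULT_POSITION_DIM = 100


@dataclass(frozen=True)
class PositionSequence:
    """Signed token offsets to an entity span, clipped to [-clip, clip]."""

    values: tuple[int, ...]
    clip: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", tuple(int(v) for v in self.values))
        if any(abs(v) > self.clip for v in self.values):
            raise ValueError("position value exceeds clip bound")

    def indices(self) -> np.ndarray:
        """Embedding-table row indices: offset + clip, in [0, 2*clip]."""
        return np.asarray(self.values, dtype=np.int64) + self.clip


def relative_positions(n: int, span: EntitySpan, clip: int = DEFAULT_CLIP) -> PositionSequence:
    """Offsets of each of ``n`` tokens to the span: i-start before, 0 inside,
    i-(end-1) after, then clipped."""
    if not (0 <= span.start < span.end <= n):
        raise ValueError(f"span [{span.start},{span.end}) out of range for n={n}")
    i = np.arange(n)
    vals = np.where(
        i < span.start, i - span.start, np.where(i >= span.end, i - (span.end - 1), 0)
    )
    vals = np.clip(vals, -clip, clip)
    return PositionSequence(tuple(int(v) for v in vals), clip)


def _hash_rng(token: str, salt: str = "") -> np.random.Generator:
    return np.random.default_rng(zlib.crc32((salt + token).encode("utf-8")))


def _random_fixed_vector(token: str, dim: int) -> np.ndarray:
    return _hash_rng(token, "oov:").standard_normal(dim) / np.sqrt(dim)


def _subword_vector(token: str, dim: int) -> np.ndarray:
    """FastText-style OOV vector: mean of hash-seeded character n-gram vectors,
    n in [3, 6], over the boundary-marked token ``<token>``."""
    marked = f"<{token}>"
    grams = [
        marked[i : i + n]
        for n in range(3, 7)
        for i in range(len(marked) - n + 1)
    ]
    if not grams:
        return _random_fixed_vector(token, dim)
    vecs = [_hash_rng(g, "ng:").standard_normal(dim) / np.sqrt(dim) for g in grams]
    return np.mean(vecs, axis=0)


@dataclass
class EmbeddingTables:
    """Word-embedding matrix with vocabulary, plus the shared position table.

    The position table is shared between the cannabis- and depression-relative
    sequences and has exactly ``2*clip + 1`` rows (row = offset + clip).
    Mask tokens always have dedicated rows so masking carries learnable signal.
    """

    word_table: np.ndarray
    vocab: dict[str, int]
    position_table: np.ndarray
    clip: int = DEFAULT_CLIP
    oov_mode: str = "random-fixed"
    _oov_cache: dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if self.position_table.shape[0] != 2 * self.clip + 1:
            raise ValueError("position_table must have 2*clip+1 rows")
        if len(self.vocab) != self.word_table.shape[0]:
            raise ValueError("vocab size does not match word_table rows")
        missing = [m for m in MASK_TOKENS.values() if m not in self.vocab]
        if missing:
            raise ValueError(f"mask tokens missing from vocabulary: {missing}")
        if self.oov_mode not in ("random-fixed", "subword"):
            raise ValueError(f"unknown oov_mode {self.oov_mode!r}")

    @property
    def word_dim(self) -> int:
        return self.word_table.shape[1]

    @property
    def position_dim(self) -> int:
        return self.position_table.shape[1]

    def oov_vector(self, token: str) -> np.ndarray:
        vec = self._oov_cache.get(token)
        if vec is None:
            fn = _subword_vector if self.oov_mode == "subword" else _random_fixed_vector
            vec = fn(token, self.word_dim)
            self._oov_cache[token] = vec
        return vec

    @classmethod
    def random_init(
        cls,
        vocab_tokens,
        word_dim: int = 16,
        position_dim: int = 8,
        clip: int = DEFAULT_CLIP,
        seed: int = 0,
        oov_mode: str = "random-fixed",
    ) -> "EmbeddingTables":
        """Small randomly initialized tables (test profile; no vector download)."""
        tokens = list(dict.fromkeys(list(MASK_TOKENS.values()) + list(vocab_tokens)))
        rng = np.random.default_rng(seed)
        scale_w, scale_p = 1 / np.sqrt(word_dim), 1 / np.sqrt(position_dim)
        return cls(
            word_table=rng.standard_normal((len(tokens), word_dim)) * scale_w,
            vocab={t: i for i, t in enumerate(tokens)},
            position_table=rng.standard_normal((2 * clip + 1, position_dim)) * scale_p,
            clip=clip,
            oov_mode=oov_mode,
        )

    @classmethod
    def from_word2vec(
        cls,
        path,
        position_dim: int = DEFAULT_POSITION_DIM,
        clip: int = DEFAULT_CLIP,
        seed: int = 0,
        oov_mode: str = "subword",
    ) -> "EmbeddingTables":
        """Load a text-format word2vec/FastText file (optional count header),
        appending learned rows for the mask tokens."""
        vocab: dict[str, int] = {}
        rows: list[np.ndarray] = []
        with open(path, encoding="utf-8") as fh:
            first = fh.readline().split()
            if len(first) == 2 and all(p.isdigit() for p in first):
                pass  # header line: vocab size, dim
            elif first:
                vocab[first[0]] = 0
                rows.append(np.asarray(first[1:], dtype=np.float64))
            for line in fh:
                parts = line.rstrip("\n").split(" ")
                if len(parts) < 2:
                    continue
                vocab[parts[0]] = len(rows)
                rows.append(np.asarray(parts[1:], dtype=np.float64))
        if not rows:
            raise ValueError(f"no vectors found in {path}")
        dim = rows[0].shape[0]
        rng = np.random.default_rng(seed)
        for mask in MASK_TOKENS.values():
            if mask not in vocab:
                vocab[mask] = len(rows)
                rows.append(rng.standard_normal(dim) / np.sqrt(dim))
        return cls(
            word_table=np.vstack(rows),
            vocab=vocab,
            position_table=rng.standard_normal((2 * clip + 1, position_dim)) / np.sqrt(position_dim),
            clip=clip,
            oov_mode=oov_mode,
        )


def embed_words(tokens, tables: EmbeddingTables) -> np.ndarray:
    """Map tokens to word vectors: table rows in-vocabulary, deterministic
    OOV vectors (``subword`` n-gram averaging or ``random-fixed`` hashing)."""
    out = np.empty((len(tokens), tables.word_dim))
    for i, tok in enumerate(tokens):
        idx = tables.vocab.get(tok)
        out[i] = tables.word_table[idx] if idx is not None else tables.oov_vector(tok)
    return out


def embed_positions(seq: PositionSequence, tables: EmbeddingTables) -> np.ndarray:
    if seq.clip != tables.clip:
        raise ValueError("position sequence clip differs from table clip")
    return tables.position_table[seq.indices()]


def encode(
    tokens,
    cannabis_span: EntitySpan,
    depression_span: EntitySpan,
    tables: EmbeddingTables,
) -> np.ndarray:
    """Per-token concatenation [word ⊕ cannabis-position ⊕ depression-position].

    Output shape (n, word_dim + 2*position_dim).
    """
    n = len(tokens)
    pc = relative_positions(n, cannabis_span, tables.clip)
    pd = relative_positions(n, depression_span, tables.clip)
    return np.concatenate(
        [embed_words(tokens, tables), embed_positions(pc, tables), embed_positions(pd, tables)],
        axis=1,
    )
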