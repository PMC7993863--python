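"""Locate and mask cannabis/depression mentions via fuzzy lexicon matching.

Every n-gram of the tokenized text (n up to the longest lexicon surface) is
compared against every lexicon surface by character-level Levenshtein
distance on the space-joined n-gram.  A span is reported when the normalized
distance — raw distance divided by the longer string's length — falls at or
below a threshold.  Exact matching is the threshold-0 special case.  Located
spans are replaced by category mask tokens (``<cannabis>``, ``<depression>``)
so the downstream classifier learns category-level rather than lexeme-level
patterns.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import edlib

from .lexicon import Category, Lexicon

__all__ = [
    "TokenizedText",
    "EntitySpan",
    "MaskedTweet",
    "EntityAbsentError",
    "MASK_TOKENS",
    "tokenize",
    "match_entities",
    "mask_entities",
    "locate_and_mask",
    "evaluate_locator",
]

MASK_TOKENS: Mapping[Category, str] = {
    Category.CANNABIS: "<cannabis>",
    Category.DEPRESSION: "<depression>",
}

# Fuzzy (nonzero-distance) matching is only attempted for surfaces at least
# this long; very short slang ("cbd", "pot") is matched exactly so it cannot
# absorb unrelated three-letter words ("cbt", "pet") one edit away.
MIN_FUZZY_SURFACE_CHARS = 4
DEFAULT_MAX_DIST = 0.2


class EntityAbsentError(ValueError):
    """The text has no locatable span for a required category."""


@dataclass(frozen=True)
class TokenizedText:
    tokens: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "tokens", tuple(self.tokens))
        if not self.tokens or any(not t for t in self.tokens):
            raise ValueError("tokens must be non-empty strings")

    @property
    def n(self) -> int:
        return len(self.tokens)


@dataclass(frozen=True, order=True)
class EntitySpan:
    """Half-open token span [start, end) matched to a lexicon surface."""

    start: int
    end: int
    category: Category
    matched_surface: str = ""
    concept: str = ""
    distance: float = 0.0

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid span [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "EntitySpan") -> bool:
        return self.start < other.end and other.start < self.end

    def key(self) -> tuple[int, int, Category]:
        return (self.start, self.end, self.category)


@dataclass(frozen=True)
class MaskedTweet:
    """Token sequence after masking, with the two selected entity spans.

    Span indices refer to the masked (shortened) sequence; each masked span
    has length 1 and its token is the category mask.
    """

    tokens: tuple[str, ...]
    cannabis_span: EntitySpan
    depression_span: EntitySpan

    def __post_init__(self) -> None:
        object.__setattr__(self, "tokens", tuple(self.tokens))
        for span, cat in (
            (self.cannabis_span, Category.CANNABIS),
            (self.depression_span, Category.DEPRESSION),
        ):
            if span.length != 1 or self.tokens[span.start] != MASK_TOKENS[cat]:
                raise ValueError(f"{cat.value} span does not cover its mask token")
        if self.cannabis_span.overlaps(self.depression_span):
            raise ValueError("masked spans overlap")

    @property
    def n(self) -> int:
        return len(self.tokens)


_URL = re.compile(r"https?://\S+|www\.\S+")
_HANDLE = re.compile(r"@\w+")
_MASK = re.compile(r"<(?:cannabis|depression|user|url)>")
_WORD = re.compile(r"<(?:cannabis|depression|user|url)>|\w+(?:'\w+)?|[^\w\s]")


def tokenize(text: str) -> TokenizedText:
    """Lowercase, collapse URLs/handles to placeholders, split punctuation.

    Mask/placeholder tokens (``<cannabis>`` etc.) survive intact; everything
    else is split into word and single-punctuation tokens.
    """
    if not text or not text.strip():
        raise ValueError("cannot tokenize empty text")
    text = _URL.sub(" <url> ", text)
    text = _HANDLE.sub(" <user> ", text)
    tokens = _WORD.findall(text.lower())
    return TokenizedText(tuple(tokens))


def _norm_distance(a: str, b: str) -> float:
    if a == b:
        return 0.0
    d = edlib.align(a, b, task="distance")["editDistance"]
    return d / max(len(a), len(b))


def _candidate_spans(t: TokenizedText, lex: Lexicon, max_dist: float) -> list[EntitySpan]:
    """All spans within threshold, one best lexicon entry per (start, end, category)."""
    best: dict[tuple[int, int, Category], EntitySpan] = {}
    for n in range(1, min(lex.max_surface_tokens, t.n) + 1):
        for start in range(t.n - n + 1):
            ngram = " ".join(t.tokens[start : start + n])
            for entry in lex:
                if max_dist == 0 or len(entry.surface) < MIN_FUZZY_SURFACE_CHARS:
                    dist = 0.0 if ngram == entry.surface else 1.0
                else:
                    dist = _norm_distance(ngram, entry.surface)
                if dist <= max_dist:
                    span = EntitySpan(
                        start, start + n, entry.category, entry.surface, entry.concept, dist
                    )
                    key = span.key()
                    prev = best.get(key)
                    if prev is None or dist < prev.distance:
                        best[key] = span
    return list(best.values())


def _resolution_rank(s: EntitySpan) -> tuple:
    # lower distance first, then longer span, then leftmost
    return (s.distance, -s.length, s.start, s.category.value)


def resolve_overlaps(spans: Iterable[EntitySpan]) -> set[EntitySpan]:
    """Greedy non-overlapping selection: lower distance, longer, leftmost."""
    chosen: list[EntitySpan] = []
    for span in sorted(spans, key=_resolution_rank):
        if not any(span.overlaps(c) for c in chosen):
            chosen.append(span)
    return set(chosen)


def match_entities(
    t: TokenizedText,
    lex: Lexicon,
    max_dist: float = DEFAULT_MAX_DIST,
    *,
    resolve: bool = True,
) -> set[EntitySpan]:
    """Fuzzy-match every n-gram against the lexicon; return spans within threshold.

    ``resolve=False`` returns the raw candidate set before overlap
    resolution (used by the threshold-monotonicity property and the exact
    matcher equivalence check).
    """
    if not 0 <= max_dist < 0.5:
        raise ValueError("max_dist must lie in [0, 0.5)")
    cands = _candidate_spans(t, lex, max_dist)
    return resolve_overlaps(cands) if resolve else set(cands)


def _select_for_category(spans: Iterable[EntitySpan], category: Category) -> EntitySpan:
    in_cat = [s for s in spans if s.category == category]
    if not in_cat:
        raise EntityAbsentError(f"no {category.value} span located")
    return min(in_cat, key=_resolution_rank)


def mask_entities(t: TokenizedText, spans: Iterable[EntitySpan]) -> MaskedTweet:
    """Replace the best span per category with its mask token.

    One cannabis and one depression span are selected (lowest distance, then
    longest, then leftmost); each selected span collapses to a single mask
    token, and span indices are recomputed for the shortened sequence.
    Raises :class:`EntityAbsentError` if a category has no span.
    """
    spans = list(spans)
    c_span = _select_for_category(spans, Category.CANNABIS)
    d_span = _select_for_category(spans, Category.DEPRESSION)
    if c_span.overlaps(d_span):
        raise ValueError("selected cannabis and depression spans overlap")

    out: list[str] = []
    new_pos: dict[Category, int] = {}
    selected = sorted((c_span, d_span), key=lambda s: s.start)
    i = 0
    for span in selected:
        out.extend(t.tokens[i : span.start])
        new_pos[span.category] = len(out)
        out.append(MASK_TOKENS[span.category])
        i = span.end
    out.extend(t.tokens[i:])

    def shifted(span: EntitySpan) -> EntitySpan:
        p = new_pos[span.category]
        return replace(span, start=p, end=p + 1)

    return MaskedTweet(tuple(out), shifted(c_span), shifted(d_span))


def locate_and_mask(
    text: str, lex: Lexicon, max_dist: float = DEFAULT_MAX_DIST
) -> MaskedTweet:
    """Tokenize, match and mask in one step (the model's preprocessing path)."""
    t = tokenize(text)
    return mask_entities(t, match_entities(t, lex, max_dist))


def evaluate_locator(
    predicted: Mapping[object, Iterable[EntitySpan]],
    gold: Mapping[object, Iterable[EntitySpan]],
) -> tuple[float, float, float]:
    """Micro-averaged span precision/recall/F-score, in percent.

    A predicted span counts as correct iff (start, end, category) all match
    a gold span of the same record.  With no predictions, precision is
    reported as 0 by convention.
    """
    if set(predicted) != set(gold):
        raise ValueError("predicted and gold record ids differ")
    tp = n_pred = n_gold = 0
    for rid in gold:
        gold_keys = {s.key() for s in gold[rid]}
        pred_keys = {s.key() for s in predicted[rid]}
        tp += len(gold_keys & pred_keys)
        n_pred += len(pred_keys)
        n_gold += len(gold_keys)
    p = 100.0 * tp / n_pred if n_pred else 0.0
    r = 100.0 * tp / n_gold if n_gold else 0.0
    f = 2 * p * r / (p + r) if p + r else 0.0
    return p, r, f
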