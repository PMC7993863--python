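"""Flat drug/mental-health lexicon: surface forms mapped to canonical concepts.

The locator needs only the lexical layer of a domain ontology: a table of
(surface form, canonical concept, category) rows covering both formal terms
and slang/street names for cannabis products and depressive states.  The
class hierarchy and inter-concept relations of a full ontology are out of
scope here.
"""

from __future__ import annotations

import csv
import json
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "Category",
    "LexiconEntry",
    "Lexicon",
    "LexiconError",
    "load_lexicon",
    "write_lexicon",
    "fixture_lexicon",
]


class Category(str, Enum):
    CANNABIS = "CANNABIS"
    DEPRESSION = "DEPRESSION"


class LexiconError(ValueError):
    """Malformed lexicon file or invariant violation."""


_WS = re.compile(r"\s+")


def normalize_surface(surface: str) -> str:
    """Lowercase and collapse all whitespace runs to single spaces."""
    return _WS.sub(" ", surface.strip().lower())


@dataclass(frozen=True)
class LexiconEntry:
    """One surface form with its canonical concept and entity category."""

    surface: str
    concept: str
    category: Category

    def __post_init__(self) -> None:
        norm = normalize_surface(self.surface)
        if not norm:
            raise LexiconError("empty surface form")
        object.__setattr__(self, "surface", norm)
        object.__setattr__(self, "category", Category(self.category))

    @property
    def n_tokens(self) -> int:
        return len(self.surface.split(" "))


@dataclass
class Lexicon:
    """Validated collection of lexicon entries covering both categories."""

    entries: tuple[LexiconEntry, ...]
    max_surface_tokens: int = field(init=False)

    def __post_init__(self) -> None:
        self.entries = tuple(self.entries)
        if not self.entries:
            raise LexiconError("lexicon is empty")
        seen: set[tuple[str, Category]] = set()
        for e in self.entries:
            key = (e.surface, e.category)
            if key in seen:
                raise LexiconError(f"duplicate entry {key!r}")
            seen.add(key)
        categories = {e.category for e in self.entries}
        missing = set(Category) - categories
        if missing:
            names = ", ".join(sorted(c.value for c in missing))
            raise LexiconError(f"lexicon has no entries for category: {names}")
        self.max_surface_tokens = max(e.n_tokens for e in self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def by_category(self, category: Category) -> tuple[LexiconEntry, ...]:
        category = Category(category)
        return tuple(e for e in self.entries if e.category == category)


def _entries_from_rows(rows: Iterable[tuple[str, str, str]], source: str) -> list[LexiconEntry]:
    entries = []
    for lineno, (surface, concept, category) in rows:
        try:
            cat = Category(category.strip().upper())
        except ValueError:
            raise LexiconError(
                f"{source}:{lineno}: unknown category {category!r} "
                f"(expected CANNABIS or DEPRESSION)"
            ) from None
        try:
            entries.append(LexiconEntry(surface, concept.strip(), cat))
        except LexiconError as exc:
            raise LexiconError(f"{source}:{lineno}: {exc}") from None
    return entries


def load_lexicon(path: str | Path) -> Lexicon:
    """Read a lexicon from CSV (``surface,concept,category`` header) or a JSON array.

    Surfaces are normalized (lowercase, collapsed whitespace).  Raises
    :class:`LexiconError` with the offending line for malformed records and
    for invariant violations (duplicates, a missing category).
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if text.lstrip().startswith("["):
        try:
            records = json.loads(text)
        except json.JSONDecodeError as exc:
            raise LexiconError(f"{path}: invalid JSON: {exc}") from None
        rows = []
        for i, rec in enumerate(records):
            if not isinstance(rec, dict) or not {"surface", "concept", "category"} <= rec.keys():
                raise LexiconError(f"{path}: record {i}: expected keys surface/concept/category")
            rows.append((i, (rec["surface"], rec["concept"], rec["category"])))
        return Lexicon(_entries_from_rows(rows, str(path)))

    reader = csv.reader(text.splitlines())
    try:
        header = next(reader)
    except StopIteration:
        raise LexiconError(f"{path}: empty file") from None
    if [h.strip().lower() for h in header] != ["surface", "concept", "category"]:
        raise LexiconError(f"{path}:1: expected header 'surface,concept,category', got {header!r}")
    rows = []
    for lineno, row in enumerate(reader, start=2):
        if not row or (len(row) == 1 and not row[0].strip()):
            continue
        if len(row) != 3:
            raise LexiconError(f"{path}:{lineno}: expected 3 fields, got {len(row)}")
        rows.append((lineno, tuple(row)))
    return Lexicon(_entries_from_rows(rows, str(path)))


def write_lexicon(lexicon: Lexicon, path: str | Path) -> None:
    """Write the lexicon as UTF-8 CSV; :func:`load_lexicon` round-trips it."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["surface", "concept", "category"])
        for e in lexicon:
            writer.writerow([e.surface, e.concept, e.category.value])


# Representative surface forms: formal terminology plus the slang and
# multi-token street names a real drug-abuse lexicon carries.  The fixture
# stands in for an ontology term list that is not publicly deposited.
_CANNABIS_SURFACES: Sequence[tuple[str, str]] = (
    ("weed", "cannabis"),
    ("marijuana", "cannabis"),
    ("cannabis", "cannabis"),
    ("pot", "cannabis"),
    ("ganja", "cannabis"),
    ("mary jane", "cannabis"),
    ("blunt", "cannabis_joint"),
    ("joint", "cannabis_joint"),
    ("smoking chronic", "cannabis_use"),
    ("marijuana candy", "cannabis_edible"),
    ("edibles", "cannabis_edible"),
    ("cbd oil", "cannabidiol"),
    ("medical marijuana", "medical_cannabis"),
    ("dank", "cannabis"),
    ("kush", "cannabis_strain"),
    ("indica", "cannabis_strain"),
    ("sativa", "cannabis_strain"),
    ("hash", "cannabis_resin"),
)

_DEPRESSION_SURFACES: Sequence[tuple[str, str]] = (
    ("depressed", "depression"),
    ("depression", "depression"),
    ("depressive", "depression"),
    ("major depressive episode", "major_depression"),
    ("feeling down", "depressed_mood"),
    ("hopeless", "hopelessness"),
    ("worthless", "worthlessness"),
    ("miserable", "depressed_mood"),
    ("melancholy", "depressed_mood"),
    ("low mood", "depressed_mood"),
    ("sad all the time", "persistent_sadness"),
    ("cant get out of bed", "anergia"),
)


def fixture_lexicon(seed: int = 0) -> Lexicon:
    """Deterministic mini-lexicon for tests and synthetic corpora.

    The entry set is fixed; ``seed`` only shuffles entry order so that
    downstream order-sensitivity bugs surface under different seeds.
    """
    import numpy as np

    entries = [
        LexiconEntry(s, c, Category.CANNABIS) for s, c in _CANNABIS_SURFACES
    ] + [
        LexiconEntry(s, c, Category.DEPRESSION) for s, c in _DEPRESSION_SURFACES
    ]
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(entries))
    return Lexicon(tuple(entries[i] for i in order))
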