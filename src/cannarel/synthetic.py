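"""Synthetic labeled tweets with planted cannabis/depression mentions.

The real annotated tweet corpus is not redistributable, so every other
module is exercised on template-generated records: each synthetic tweet
contains exactly one cannabis and one depression mention drawn from the
lexicon (optionally misspelled by one character edit), and its relation
label is signaled by label-specific cue phrases mirroring the annotation
scheme — help/treat/cure for Reason, causes/making-worse for Effect,
lack-of/withdrawal for Addiction, and neutral co-occurrence for Ambiguous.
Class proportions default to the 3243:707:158:1777 imbalance of the
annotated corpus, apportioned by largest remainder.
"""

from __future__ import annotations

import string
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .lexicon import Category, Lexicon
from .locator import EntitySpan
from .model import LABELS

__all__ = [
    "TemplateSpec",
    "GeneratorConfig",
    "LabeledTweet",
    "TEMPLATES",
    "largest_remainder_counts",
    "generate_corpus",
    "position_sensitive_task",
    "write_corpus",
    "read_corpus",
]

CANNABIS_SLOT = "{CANNABIS}"
DEPRESSION_SLOT = "{DEPRESSION}"


@dataclass(frozen=True)
class TemplateSpec:
    """One tweet pattern: a token sequence with one slot per entity category
    and the cue phrases that make its label recognizable."""

    label: str
    pattern: tuple[str, ...]
    cues: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}")
        for slot in (CANNABIS_SLOT, DEPRESSION_SLOT):
            if list(self.pattern).count(slot) != 1:
                raise ValueError(f"template must contain exactly one {slot}")


TEMPLATES: tuple[TemplateSpec, ...] = (
    # Reason: cannabis used to help/treat/cure depression
    TemplateSpec("Reason", ("{CANNABIS}", "really", "helps", "my", "{DEPRESSION}"), ("helps",)),
    TemplateSpec("Reason", ("i", "treat", "my", "{DEPRESSION}", "with", "{CANNABIS}"), ("treat",)),
    TemplateSpec("Reason", ("{CANNABIS}", "is", "the", "only", "cure", "for", "my", "{DEPRESSION}"), ("cure",)),
    TemplateSpec("Reason", ("some", "{CANNABIS}", "brings", "relief", "when", "the", "{DEPRESSION}", "hits"), ("relief",)),
    # Effect: cannabis causes depression or worsens it
    TemplateSpec("Effect", ("{CANNABIS}", "is", "making", "my", "{DEPRESSION}", "worse"), ("making", "worse")),
    TemplateSpec("Effect", ("i", "think", "{CANNABIS}", "causes", "my", "{DEPRESSION}"), ("causes",)),
    TemplateSpec("Effect", ("i", "blame", "{CANNABIS}", "for", "this", "{DEPRESSION}"), ("blame",)),
    # Addiction: lack of cannabis leads to depressive mood
    TemplateSpec("Addiction", ("the", "lack", "of", "{CANNABIS}", "has", "me", "{DEPRESSION}"), ("lack",)),
    TemplateSpec("Addiction", ("ran", "out", "of", "{CANNABIS}", "and", "now", "the", "{DEPRESSION}", "is", "back"), ("ran", "out")),
    TemplateSpec("Addiction", ("withdrawal", "from", "{CANNABIS}", "leaves", "me", "{DEPRESSION}"), ("withdrawal",)),
    # Ambiguous: co-occurrence without a relation cue
    TemplateSpec("Ambiguous", ("{CANNABIS}", "and", "{DEPRESSION}", "in", "the", "same", "week"), ()),
    TemplateSpec("Ambiguous", ("me", "with", "my", "{DEPRESSION}", "and", "some", "{CANNABIS}", "tonight"), ()),
    TemplateSpec("Ambiguous", ("thinking", "about", "{CANNABIS}", "while", "this", "{DEPRESSION}", "sits", "here"), ()),
)

# Neutral filler tokens used as distractor insertions; none appears as a cue.
_FILLERS = ("lol", "honestly", "today", "man", "fr", "tbh", "again", "mood", "ugh", "literally")


def _check_cue_disjointness() -> None:
    by_label: dict[str, set[str]] = {}
    for t in TEMPLATES:
        by_label.setdefault(t.label, set()).update(t.cues)
    labels = list(by_label)
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            shared = by_label[a] & by_label[b]
            if shared:
                raise AssertionError(f"cue phrases shared between {a} and {b}: {shared}")


_check_cue_disjointness()

DEFAULT_CLASS_WEIGHTS: tuple[float, ...] = (3243.0, 707.0, 158.0, 1777.0)


@dataclass(frozen=True)
class GeneratorConfig:
    n_records: int = 5885
    class_weights: tuple[float, ...] = DEFAULT_CLASS_WEIGHTS
    misspelling_rate: float = 0.1
    distractor_rate: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_records < 1:
            raise ValueError("n_records must be positive")
        if len(self.class_weights) != len(LABELS) or any(w <= 0 for w in self.class_weights):
            raise ValueError("class_weights must be positive, one per label")
        for rate in (self.misspelling_rate, self.distractor_rate):
            if not 0 <= rate <= 1:
                raise ValueError("rates must lie in [0, 1]")


@dataclass(frozen=True)
class LabeledTweet:
    """One synthetic record: raw text, gold token spans, relation label."""

    id: str
    text: str
    label: str
    cannabis_span: EntitySpan
    depression_span: EntitySpan


def largest_remainder_counts(n: int, weights: Sequence[float]) -> list[int]:
    """Apportion ``n`` into integer counts proportional to ``weights``."""
    w = np.asarray(weights, dtype=float)
    quota = n * w / w.sum()
    counts = np.floor(quota).astype(int)
    remainder = n - counts.sum()
    order = np.argsort(-(quota - counts), kind="stable")
    for i in order[:remainder]:
        counts[i] += 1
    return counts.tolist()


# Misspelling keeps surfaces at normalized distance <= 1/5 from the lexicon
# entry so the locator's default threshold still recovers them.
_MIN_MISSPELL_CHARS = 5


def _misspell(surface: str, rng: np.random.Generator) -> str:
    """One random character insert/delete/substitute, never touching spaces."""
    if len(surface) < _MIN_MISSPELL_CHARS:
        return surface
    letters = string.ascii_lowercase
    positions = [i for i, ch in enumerate(surface) if ch != " "]
    op = rng.choice(["insert", "delete", "substitute"])
    if op == "insert":
        i = int(rng.integers(0, len(surface) + 1))
        return surface[:i] + letters[rng.integers(0, 26)] + surface[i:]
    i = int(positions[rng.integers(0, len(positions))])
    if op == "delete":
        out = surface[:i] + surface[i + 1 :]
    else:
        old = surface[i]
        choices = [c for c in letters if c != old]
        out = surface[:i] + choices[rng.integers(0, 25)] + surface[i + 1 :]
    # an edit must not create or destroy a token boundary
    return out if "  " not in out and not out.startswith(" ") and not out.endswith(" ") else surface


def _has_sub_surface(surface: str, all_surfaces: set[str]) -> bool:
    """True if a proper contiguous token sub-span of ``surface`` is itself a
    lexicon surface (misspelling such an entry could let the exact sub-match
    win the overlap tie-break over the fuzzy full match)."""
    toks = surface.split(" ")
    for n in range(1, len(toks)):
        for i in range(len(toks) - n + 1):
            if " ".join(toks[i : i + n]) in all_surfaces:
                return True
    return False


def _pick_surface(lex: Lexicon, category: Category, rng: np.random.Generator,
                  misspelling_rate: float) -> tuple[list[str], str]:
    entries = lex.by_category(category)
    all_surfaces = {e.surface for e in lex}
    entry = entries[rng.integers(0, len(entries))]
    surface = entry.surface
    if (
        misspelling_rate
        and rng.random() < misspelling_rate
        and not _has_sub_surface(surface, all_surfaces)
    ):
        surface = _misspell(surface, rng)
    return surface.split(" "), entry.surface


def _build_record(
    rid: str,
    template: TemplateSpec,
    lex: Lexicon,
    cfg: GeneratorConfig,
    rng: np.random.Generator,
) -> LabeledTweet:
    c_tokens, _ = _pick_surface(lex, Category.CANNABIS, rng, cfg.misspelling_rate)
    d_tokens, _ = _pick_surface(lex, Category.DEPRESSION, rng, cfg.misspelling_rate)
    tokens: list[str] = []
    spans: dict[Category, tuple[int, int]] = {}
    for tok in template.pattern:
        if tok == CANNABIS_SLOT:
            spans[Category.CANNABIS] = (len(tokens), len(tokens) + len(c_tokens))
            tokens.extend(c_tokens)
        elif tok == DEPRESSION_SLOT:
            spans[Category.DEPRESSION] = (len(tokens), len(tokens) + len(d_tokens))
            tokens.extend(d_tokens)
        else:
            tokens.append(tok)

    if cfg.distractor_rate:
        # insert fillers at gaps outside entity spans, back to front so
        # earlier span indices stay valid while later ones are shifted
        inside = set()
        for s, e in spans.values():
            inside.update(range(s + 1, e))
        gaps = [g for g in range(len(tokens) + 1) if g not in inside]
        for g in sorted(gaps, reverse=True):
            if rng.random() < cfg.distractor_rate:
                filler = _FILLERS[rng.integers(0, len(_FILLERS))]
                tokens.insert(g, filler)
                for cat, (s, e) in spans.items():
                    if g <= s:
                        spans[cat] = (s + 1, e + 1)

    c_start, c_end = spans[Category.CANNABIS]
    d_start, d_end = spans[Category.DEPRESSION]
    return LabeledTweet(
        id=rid,
        text=" ".join(tokens),
        label=template.label,
        cannabis_span=EntitySpan(c_start, c_end, Category.CANNABIS),
        depression_span=EntitySpan(d_start, d_end, Category.DEPRESSION),
    )


def generate_corpus(lex: Lexicon, cfg: GeneratorConfig) -> list[LabeledTweet]:
    """Deterministic synthetic corpus with exact largest-remainder class counts."""
    rng = np.random.default_rng(cfg.seed)
    counts = largest_remainder_counts(cfg.n_records, cfg.class_weights)
    labels = [lab for lab, c in zip(LABELS, counts) for _ in range(c)]
    rng.shuffle(labels)
    by_label: dict[str, list[TemplateSpec]] = {}
    for t in TEMPLATES:
        by_label.setdefault(t.label, []).append(t)
    records = []
    for i, lab in enumerate(labels):
        template = by_label[lab][rng.integers(0, len(by_label[lab]))]
        records.append(_build_record(f"r{i:05d}", template, lex, cfg, rng))
    return records


# Cue token for the position-sensitive task; not a template cue, filler or
# lexicon surface, so only its side relative to the cannabis mask is
# informative.
_POSITION_CUE = "flare"


def position_sensitive_task(lex: Lexicon, cfg: GeneratorConfig) -> list[LabeledTweet]:
    """Binary task where only the cue's side relative to the cannabis mention
    decides the label.

    The cue token appears exactly twice per record: once immediately
    adjacent to the cannabis span (before it → "Reason", after it →
    "Effect") and once more as a distractor far from the span, so
    bag-of-words counts are identical across the two labels and only
    position information disambiguates.
    """
    rng = np.random.default_rng(cfg.seed)
    n_each = cfg.n_records // 2
    labels = ["Reason"] * n_each + ["Effect"] * (cfg.n_records - n_each)
    rng.shuffle(labels)
    records = []
    for i, lab in enumerate(labels):
        c_tokens, _ = _pick_surface(lex, Category.CANNABIS, rng, 0.0)
        d_tokens, _ = _pick_surface(lex, Category.DEPRESSION, rng, 0.0)
        pre = [_FILLERS[rng.integers(0, len(_FILLERS))] for _ in range(int(rng.integers(2, 5)))]
        mid = [_FILLERS[rng.integers(0, len(_FILLERS))] for _ in range(int(rng.integers(2, 4)))]
        post = [_FILLERS[rng.integers(0, len(_FILLERS))] for _ in range(int(rng.integers(2, 4)))]
        # distractor cue at least two tokens away from the cannabis span
        if rng.random() < 0.5:
            pre.insert(int(rng.integers(0, max(1, len(pre) - 1))), _POSITION_CUE)
        else:
            post.insert(int(rng.integers(1, len(post) + 1)), _POSITION_CUE)
        tokens = list(pre)
        if lab == "Reason":
            tokens.append(_POSITION_CUE)
            c_start = len(tokens)
            tokens.extend(c_tokens)
        else:
            c_start = len(tokens)
            tokens.extend(c_tokens)
            tokens.append(_POSITION_CUE)
        c_end = c_start + len(c_tokens)
        tokens.extend(mid)
        d_start = len(tokens)
        tokens.extend(d_tokens)
        d_end = d_start + len(d_tokens)
        tokens.extend(post)
        records.append(
            LabeledTweet(
                id=f"p{i:05d}",
                text=" ".join(tokens),
                label=lab,
                cannabis_span=EntitySpan(c_start, c_end, Category.CANNABIS),
                depression_span=EntitySpan(d_start, d_end, Category.DEPRESSION),
            )
        )
    return records


# -- TSV I/O ---------------------------------------------------------------

_COLUMNS = ("id", "text", "label", "c_start", "c_end", "d_start", "d_end")


def _escape(text: str) -> str:
    return text.replace("\\", "\\\\").replace("\t", "\\t").replace("\n", "\\n")


def _unescape(text: str) -> str:
    out: list[str] = []
    i = 0
    while i < len(text):
        ch = text[i]
        if ch == "\\" and i + 1 < len(text):
            nxt = text[i + 1]
            out.append({"t": "\t", "n": "\n", "\\": "\\"}.get(nxt, "\\" + nxt))
            i += 2
        else:
            out.append(ch)
            i += 1
    return "".join(out)


def write_corpus(records: Sequence[LabeledTweet], path: str | Path) -> None:
    """Lossless TSV dump: ``id text label c_start c_end d_start d_end`` with
    backslash-escaped tabs/newlines in the text column."""
    path = Path(path)
    lines = ["\t".join(_COLUMNS)]
    for r in records:
        lines.append(
            "\t".join(
                [
                    r.id,
                    _escape(r.text),
                    r.label,
                    str(r.cannabis_span.start),
                    str(r.cannabis_span.end),
                    str(r.depression_span.start),
                    str(r.depression_span.end),
                ]
            )
        )
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_corpus(path: str | Path) -> list[LabeledTweet]:
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    if not lines or lines[0].split("\t") != list(_COLUMNS):
        raise ValueError(f"{path}:1: expected header {'	'.join(_COLUMNS)!r}")
    records = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line:
            continue
        parts = line.split("\t")
        if len(parts) != len(_COLUMNS):
            raise ValueError(f"{path}:{lineno}: expected {len(_COLUMNS)} fields, got {len(parts)}")
        rid, text, label, cs, ce, ds, de = parts
        if label not in LABELS:
            raise ValueError(f"{path}:{lineno}: unknown label {label!r}")
        try:
            cs, ce, ds, de = int(cs), int(ce), int(ds), int(de)
        except ValueError:
            raise ValueError(f"{path}:{lineno}: non-integer span bound") from None
        records.append(
            LabeledTweet(
                id=rid,
                text=_unescape(text),
                label=label,
                cannabis_span=EntitySpan(cs, ce, Category.CANNABIS),
                depression_span=EntitySpan(ds, de, Category.DEPRESSION),
            )
        )
    return records
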