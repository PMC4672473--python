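"""Convert open-ended VA narratives into binary text items.

Pipeline: lowercase, split on non-alphabetic characters, drop short
tokens, stem with the classic Porter suffix-stripping algorithm, merge
stem families that differ only by a trailing ``i`` (the Porter y->i
family: "injury"/"injuries" -> "injuri", "injured" -> "injur" are one
item), apply user-configured synonym groups (e.g. "fire" and "burn" form
one item), drop stems occurring fewer than ``min_count`` times in the
corpus, and suppress blocklisted items.

The blocklist replaces clinical plausibility review: an entry
``(text_item, '*')`` removes the item everywhere (applied here); an entry
``(text_item, cause)`` suppresses only that item-cause tariff and is
applied at training time.  The canonical example is the narrative term
"road", plausible for road-traffic deaths but spuriously associated with
cancers through a hospital name.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .data import Dataset, Item, VARecord

TEXT_PREFIX = "word_"
ALL_CAUSES = "*"

_VOWELS = "aeiou"
_TOKEN_RE = re.compile(r"[a-z]+")
MIN_TOKEN_LEN = 3


# ---------------------------------------------------------------------------
# Porter (1980) stemmer


def _is_cons(word: str, i: int) -> bool:
    c = word[i]
    if c in _VOWELS:
        return False
    if c == "y":
        return i == 0 or not _is_cons(word, i - 1)
    return True


def _shape(word: str) -> str:
    return "".join("c" if _is_cons(word, i) else "v" for i in range(len(word)))


def _measure(stem: str) -> int:
    """Number of vowel-consonant sequences (the m of the algorithm)."""
    return len(re.findall(r"v+c+", _shape(stem)))


def _has_vowel(stem: str) -> bool:
    return "v" in _shape(stem)


def _ends_double_cons(word: str) -> bool:
    return (
        len(word) >= 2
        and word[-1] == word[-2]
        and _is_cons(word, len(word) - 1)
    )


def _ends_cvc(word: str) -> bool:
    if len(word) < 3:
        return False
    return (
        _is_cons(word, len(word) - 3)
        and not _is_cons(word, len(word) - 2)
        and _is_cons(word, len(word) - 1)
        and word[-1] not in "wxy"
    )


def _replace(word: str, suffix: str, repl: str, min_measure: int) -> str | None:
    """Replace suffix if the remaining stem has measure > min_measure."""
    if not word.endswith(suffix):
        return None
    stem = word[: len(word) - len(suffix)]
    if _measure(stem) > min_measure:
        return stem + repl
    return word  # suffix matched, rule fires as no-op (stops the scan)


_STEP2 = [
    ("ational", "ate"), ("tional", "tion"), ("enci", "ence"), ("anci", "ance"),
    ("izer", "ize"), ("abli", "able"), ("alli", "al"), ("entli", "ent"),
    ("eli", "e"), ("ousli", "ous"), ("ization", "ize"), ("ation", "ate"),
    ("ator", "ate"), ("alism", "al"), ("iveness", "ive"), ("fulness", "ful"),
    ("ousness", "ous"), ("aliti", "al"), ("iviti", "ive"), ("biliti", "ble"),
]
_STEP3 = [
    ("icate", "ic"), ("ative", ""), ("alize", "al"), ("iciti", "ic"),
    ("ical", "ic"), ("ful", ""), ("ness", ""),
]
_STEP4 = [
    "al", "ance", "ence", "er", "ic", "able", "ible", "ant", "ement",
    "ment", "ent", "ion", "ou", "ism", "ate", "iti", "ous", "ive", "ize",
]


def porter_stem(word: str) -> str:
    """Stem one lowercase alphabetic token with the Porter algorithm."""
    w = word
    if len(w) <= 2:
        return w

    # step 1a
    if w.endswith("sses"):
        w = w[:-2]
    elif w.endswith("ies"):
        w = w[:-2]
    elif w.endswith("ss"):
        pass
    elif w.endswith("s"):
        w = w[:-1]

    # step 1b
    if w.endswith("eed"):
        if _measure(w[:-3]) > 0:
            w = w[:-1]
    else:
        stripped = None
        if w.endswith("ed") and _has_vowel(w[:-2]):
            stripped = w[:-2]
        elif w.endswith("ing") and _has_vowel(w[:-3]):
            stripped = w[:-3]
        if stripped is not None:
            w = stripped
            if w.endswith(("at", "bl", "iz")):
                w += "e"
            elif _ends_double_cons(w) and not w.endswith(("l", "s", "z")):
                w = w[:-1]
            elif _measure(w) == 1 and _ends_cvc(w):
                w += "e"

    # step 1c
    if w.endswith("y") and _has_vowel(w[:-1]):
        w = w[:-1] + "i"

    # step 2
    for suf, repl in _STEP2:
        if w.endswith(suf):
            w = _replace(w, suf, repl, 0)
            break

    # step 3
    for suf, repl in _STEP3:
        if w.endswith(suf):
            w = _replace(w, suf, repl, 0)
            break

    # step 4
    for suf in _STEP4:
        if w.endswith(suf):
            stem = w[: len(w) - len(suf)]
            if suf == "ion" and not stem.endswith(("s", "t")):
                break
            if _measure(stem) > 1:
                w = stem
            break

    # step 5a
    if w.endswith("e"):
        stem = w[:-1]
        m = _measure(stem)
        if m > 1 or (m == 1 and not _ends_cvc(stem)):
            w = stem
    # step 5b
    if w.endswith("ll") and _measure(w) > 1:
        w = w[:-1]

    return w


# ---------------------------------------------------------------------------
# Configuration objects


@dataclass(frozen=True)
class SynonymGroups:
    """Map canonical item stem -> set of surface stems merged into it."""

    groups: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for canonical, stems in self.groups.items():
            overlap = seen & set(stems)
            if overlap:
                raise ValueError(f"stems in two synonym groups: {sorted(overlap)}")
            seen |= set(stems)

    def canonical_map(self) -> dict[str, str]:
        out: dict[str, str] = {}
        for canonical, stems in self.groups.items():
            for s in stems:
                out[s] = canonical
            out.setdefault(canonical, canonical)
        return out

    @classmethod
    def from_csv(cls, path: str | Path) -> "SynonymGroups":
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        groups: dict[str, set[str]] = {}
        for r in df.itertuples():
            groups.setdefault(r.canonical_item, set()).add(r.stem)
        return cls({k: frozenset(v) for k, v in groups.items()})


@dataclass(frozen=True)
class Blocklist:
    """Set of (text-item-id, cause-id-or-'*') pairs to suppress."""

    pairs: frozenset[tuple[str, str]] = field(default_factory=frozenset)

    def blocked_everywhere(self) -> set[str]:
        return {item for item, cause in self.pairs if cause == ALL_CAUSES}

    def cause_pairs(self) -> set[tuple[str, str]]:
        return {(item, cause) for item, cause in self.pairs if cause != ALL_CAUSES}

    @classmethod
    def from_csv(cls, path: str | Path) -> "Blocklist":
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        return cls(frozenset(zip(df["text_item"], df["cause_id"])))


# ---------------------------------------------------------------------------
# Extraction


def tokenize(text: str) -> list[str]:
    return [t for t in _TOKEN_RE.findall(text.lower()) if len(t) >= MIN_TOKEN_LEN]


def _conflate_trailing_i(stems_per_doc: list[list[str]]) -> list[list[str]]:
    """Merge stem pairs (s, s+'i') onto the with-i form, corpus-wide."""
    vocab = {s for doc in stems_per_doc for s in doc}
    remap = {s: s + "i" for s in vocab if s + "i" in vocab}
    if not remap:
        return stems_per_doc
    return [[remap.get(s, s) for s in doc] for doc in stems_per_doc]


def extract_text_items(
    narratives: Sequence[tuple[str, str]],
    min_count: int = 50,
    groups: SynonymGroups | None = None,
    blocklist: Blocklist | None = None,
) -> pd.DataFrame:
    """Binary record x text-item matrix from (record id, narrative) pairs.

    A record endorses an item iff at least one member stem occurs in its
    narrative.  Stems with total corpus occurrences below ``min_count``
    are dropped; blocklisted ``(item, '*')`` pairs never appear.
    """
    if min_count < 1:
        raise ValueError(f"min_count must be >= 1, got {min_count}")
    ids = [rid for rid, _ in narratives]
    stems_per_doc = [
        [porter_stem(t) for t in tokenize(text or "")] for _, text in narratives
    ]
    stems_per_doc = _conflate_trailing_i(stems_per_doc)
    cmap = (groups or SynonymGroups()).canonical_map()
    stems_per_doc = [[cmap.get(s, s) for s in doc] for doc in stems_per_doc]

    counts: dict[str, int] = {}
    for doc in stems_per_doc:
        for s in doc:
            counts[s] = counts.get(s, 0) + 1
    blocked = (blocklist or Blocklist()).blocked_everywhere()
    kept = sorted(
        s
        for s, n in counts.items()
        if n >= min_count and TEXT_PREFIX + s not in blocked
    )
    cols = [TEXT_PREFIX + s for s in kept]
    out = pd.DataFrame(
        np.zeros((len(ids), len(cols)), dtype=np.int8),
        index=pd.Index(ids, name="id"),
        columns=cols,
    )
    col_of = {s: TEXT_PREFIX + s for s in kept}
    for rid, doc in zip(ids, stems_per_doc):
        for s in set(doc):
            c = col_of.get(s)
            if c is not None:
                out.at[rid, c] = 1
    return out


def add_text_items(
    dataset: Dataset,
    min_count: int = 50,
    groups: SynonymGroups | None = None,
    blocklist: Blocklist | None = None,
) -> Dataset:
    """Return a dataset whose dictionary and responses include text items."""
    matrix = extract_text_items(
        [(r.id, r.narrative or "") for r in dataset.records],
        min_count=min_count,
        groups=groups,
        blocklist=blocklist,
    )
    new_items = [
        Item(
            item_id=c,
            label=f"narrative term {c[len(TEXT_PREFIX):]!r}",
            source="text",
            hce_dependent=False,
            module=dataset.module,
        )
        for c in matrix.columns
        if c not in dataset.dictionary
    ]
    new_dict = dataset.dictionary.extended(new_items)
    new_records = []
    for r in dataset.records:
        extra = {c: 1 for c in matrix.columns if matrix.at[r.id, c]}
        responses = {**r.responses, **extra}
        new_records.append(
            VARecord(
                id=r.id,
                module=r.module,
                sex=r.sex,
                age=r.age,
                site=r.site,
                responses=responses,
                narrative=r.narrative,
                gold_standard=r.gold_standard,
            )
        )
    return Dataset(new_records, new_dict, dataset.causes)
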