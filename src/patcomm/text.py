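"""Lexical analysis of pattern descriptions.

Descriptions are free text; tokenization lowercases and splits on
non-alphabetic characters with no stemming or stop-word removal, so
inflected forms ("starts", "waves") stay distinct.  The module covers
lexical diversity (type-token ratio), differential word lists between two
description pools, component-specific vocabularies extracted from
single-component descriptions, and word-set presence probabilities.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field

__all__ = [
    "Description",
    "ComponentVocabulary",
    "tokenize",
    "lexical_diversity",
    "differential_words",
    "extract_component_words",
    "word_set_presence",
]

_TOKEN_RE = re.compile(r"[^a-z]+")


def tokenize(text: str) -> list[str]:
    """Lowercase, split on non-alphabetic characters, drop empties."""
    return [t for t in _TOKEN_RE.split(text.lower()) if t]


@dataclass
class Description:
    """One free-text description of a pattern.

    ``judge_rating`` is the mean judge score on the 1-5 scale used to filter
    descriptions (retain when above 3); it is carried as data only.
    """

    describer_id: str
    pattern_id: str
    text: str
    judge_rating: float | None = None
    tokens: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.tokens:
            self.tokens = tokenize(self.text)
        if self.judge_rating is not None and not (1 <= self.judge_rating <= 5):
            raise ValueError(f"judge_rating must be in [1, 5], got {self.judge_rating}")


@dataclass
class ComponentVocabulary:
    """Top-k words most specific to one base component."""

    component: str
    words: list[str]
    scores: list[float]
    flagged: bool = False  # fewer than k eligible words, or degenerate ties


def _tokens_of(item) -> list[str]:
    if isinstance(item, Description):
        return item.tokens
    if isinstance(item, str):
        return tokenize(item)
    return list(item)


def lexical_diversity(tokens) -> float:
    """Unique words divided by total words (type-token ratio), in (0, 1]."""
    tokens = _tokens_of(tokens)
    if not tokens:
        raise ValueError("lexical_diversity requires at least one token")
    return len(set(tokens)) / len(tokens)


def differential_words(descs_a, descs_b, min_count: int = 3) -> list[tuple[str, int]]:
    """Words used at least ``min_count`` times in pool A and never in pool B.

    Returns (word, count-in-A) pairs sorted by descending count then
    alphabetically.  With the default threshold this is "used more than
    twice in A but not in B".
    """
    if not descs_a or not descs_b:
        raise ValueError("both description collections must be nonempty")
    count_a = Counter(t for d in descs_a for t in _tokens_of(d))
    vocab_b = {t for d in descs_b for t in _tokens_of(d)}
    out = [(w, c) for w, c in count_a.items() if c >= min_count and w not in vocab_b]
    out.sort(key=lambda wc: (-wc[1], wc[0]))
    return out


def extract_component_words(descs_by_component: dict, k: int = 10) -> dict[str, ComponentVocabulary]:
    """Top-k component-specific words from single-component descriptions.

    For each component, words are ranked by their relative frequency in that
    component's descriptions minus the maximum relative frequency in either
    other component (relative frequencies because corpus sizes differ);
    ties break alphabetically.  A vocabulary is flagged when fewer than
    ``k`` words are eligible or when all differential scores are zero.
    """
    for comp, descs in descs_by_component.items():
        if not descs:
            raise ValueError(f"no descriptions for component {comp}")
    rel: dict[str, Counter] = {}
    totals: dict[str, int] = {}
    for comp, descs in descs_by_component.items():
        counts = Counter(t for d in descs for t in _tokens_of(d))
        rel[comp] = counts
        totals[comp] = max(sum(counts.values()), 1)
    vocab = {w for counts in rel.values() for w in counts}
    out: dict[str, ComponentVocabulary] = {}
    for comp in descs_by_component:
        others = [c for c in descs_by_component if c != comp]
        scored = []
        for w in vocab:
            f_self = rel[comp][w] / totals[comp]
            f_other = max((rel[o][w] / totals[o] for o in others), default=0.0)
            scored.append((w, f_self - f_other))
        scored.sort(key=lambda ws: (-ws[1], ws[0]))
        top = scored[:k]
        flagged = len(top) < k or all(s == 0.0 for _, s in top)
        out[comp] = ComponentVocabulary(
            component=comp,
            words=[w for w, _ in top],
            scores=[s for _, s in top],
            flagged=flagged,
        )
    return out


def word_set_presence(descriptions, word_set) -> float:
    """Fraction of descriptions containing at least one word from the set."""
    descriptions = list(descriptions)
    word_set = set(word_set)
    if not descriptions or not word_set:
        raise ValueError("descriptions and word_set must be nonempty")
    hits = sum(1 for d in descriptions if word_set & set(_tokens_of(d)))
    return hits / len(descriptions)
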