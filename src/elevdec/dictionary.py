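"""Emotion dictionary: term scores plus negator and degree-word lexicons.

A moral-elevation dictionary maps words or phrases to an integer intensity
score in {0, 1, 2}.  Scores come from re-coding mean 7-point Likert ratings
(average of "touched feeling" and "elevation" judgements): ratings below 2.5
score 0, ratings in the closed band [2.5, 5.5] score 1, and ratings above
5.5 score 2.  Two modifier lexicons travel with the dictionary: *negators*
(weight -1) and *degree words* (each with a positive multiplier, by default
0.75 / 1.25 / 1.5 / 2 for increasing intensity).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

__all__ = [
    "EmotionDictionary",
    "RatedTerm",
    "recode_rating",
    "build_dictionary",
    "read_dictionary",
    "write_dictionary",
    "DEFAULT_DEGREE_WORDS",
    "DEFAULT_NEGATORS",
    "NEGATOR_WEIGHT",
]

#: Weight contributed by each negator preceding an entry term.
NEGATOR_WEIGHT = -1.0

#: Default degree-word multipliers, one per intensity level.
DEFAULT_DEGREE_WORDS = {
    "a little": 0.75,
    "more": 1.25,
    "very": 1.5,
    "most": 2.0,
}

#: Default negators.
DEFAULT_NEGATORS = frozenset({"not", "no", "never"})


class DictionaryError(ValueError):
    """Invalid dictionary contents (bad score, overlapping lexicons, ...)."""


@dataclass(frozen=True)
class RatedTerm:
    """A term with its mean Likert rating in [1, 7]."""

    term: str
    mean_rating: float

    def __post_init__(self) -> None:
        if not 1.0 <= self.mean_rating <= 7.0:
            raise DictionaryError(
                f"mean_rating for {self.term!r} must lie in [1, 7], "
                f"got {self.mean_rating}"
            )


@dataclass(frozen=True)
class EmotionDictionary:
    """Scored entries plus negator and degree-word modifier lexicons.

    Parameters
    ----------
    entries
        Term -> score, score in {0, 1, 2}.
    negators
        Terms that flip the sign of the next entry term (weight -1).
    degree_words
        Term -> strictly positive multiplier.
    """

    entries: Mapping[str, int] = field(default_factory=dict)
    negators: frozenset[str] = DEFAULT_NEGATORS
    degree_words: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DEGREE_WORDS)
    )

    def __post_init__(self) -> None:
        object.__setattr__(self, "entries", dict(self.entries))
        object.__setattr__(self, "negators", frozenset(self.negators))
        object.__setattr__(self, "degree_words", dict(self.degree_words))
        for term, score in self.entries.items():
            if score not in (0, 1, 2):
                raise DictionaryError(
                    f"entry {term!r} has score {score!r}; must be 0, 1 or 2"
                )
        for term, mult in self.degree_words.items():
            if not mult > 0:
                raise DictionaryError(
                    f"degree word {term!r} has non-positive multiplier {mult}"
                )
        overlaps = (
            (set(self.entries) & self.negators)
            | (set(self.entries) & set(self.degree_words))
            | (self.negators & set(self.degree_words))
        )
        if overlaps:
            raise DictionaryError(
                "terms present in more than one lexicon: "
                + ", ".join(sorted(overlaps))
            )

    def all_terms(self) -> set[str]:
        """Union of entry, negator and degree-word terms."""
        return set(self.entries) | set(self.negators) | set(self.degree_words)

    def terms_with_score(self, score: int) -> list[str]:
        return sorted(t for t, s in self.entries.items() if s == score)


def recode_rating(mean_rating: float) -> int:
    """Re-code a mean rating in [1, 7] into a dictionary score.

    <2.5 -> 0, [2.5, 5.5] -> 1, >5.5 -> 2.  The middle band is closed at
    both ends so the three rules are exhaustive and exclusive.
    """
    if not 1.0 <= mean_rating <= 7.0:
        raise DictionaryError(f"mean_rating must lie in [1, 7], got {mean_rating}")
    if mean_rating < 2.5:
        return 0
    if mean_rating <= 5.5:
        return 1
    return 2


def build_dictionary(
    rated_terms: Iterable[RatedTerm],
    negators: Iterable[str] = DEFAULT_NEGATORS,
    degree_words: Mapping[str, float] | None = None,
) -> EmotionDictionary:
    """Build a dictionary from rated terms and modifier lexicons."""
    if degree_words is None:
        degree_words = dict(DEFAULT_DEGREE_WORDS)
    rated = list(rated_terms)
    seen: set[str] = set()
    for rt in rated:
        if rt.term in seen:
            raise DictionaryError(f"duplicate rated term {rt.term!r}")
        seen.add(rt.term)
    return EmotionDictionary(
        entries={rt.term: recode_rating(rt.mean_rating) for rt in rated},
        negators=frozenset(negators),
        degree_words=degree_words,
    )


# --- TSV serialization -------------------------------------------------------
# Dialect: UTF-8, tab-separated, header "term<TAB>role<TAB>value";
# role is entry|negator|degree; value is 0/1/2 for entries, empty for
# negators, a positive decimal for degree words.

_HEADER = "term\trole\tvalue"


def write_dictionary(d: EmotionDictionary, path: str | Path) -> None:
    """Write a dictionary as a round-trippable TSV file."""
    lines = [_HEADER]
    for term in sorted(d.entries):
        lines.append(f"{term}\tentry\t{d.entries[term]}")
    for term in sorted(d.negators):
        lines.append(f"{term}\tnegator\t")
    for term in sorted(d.degree_words):
        lines.append(f"{term}\tdegree\t{d.degree_words[term]!r}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_dictionary(path: str | Path) -> EmotionDictionary:
    """Read a dictionary TSV written by :func:`write_dictionary`."""
    text = Path(path).read_text(encoding="utf-8")
    lines = text.splitlines()
    if not lines or lines[0].rstrip() != _HEADER:
        raise DictionaryError(f"{path}: missing header {_HEADER!r}")
    entries: dict[str, int] = {}
    negators: set[str] = set()
    degree: dict[str, float] = {}
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise DictionaryError(
                f"{path}:{lineno}: expected 3 tab-separated fields, got {len(parts)}"
            )
        term, role, value = parts
        if role == "entry":
            try:
                score = int(value)
            except ValueError:
                raise DictionaryError(
                    f"{path}:{lineno}: entry score {value!r} is not an integer"
                ) from None
            if score not in (0, 1, 2):
                raise DictionaryError(
                    f"{path}:{lineno}: entry score must be 0, 1 or 2, got {score}"
                )
            entries[term] = score
        elif role == "negator":
            negators.add(term)
        elif role == "degree":
            try:
                degree[term] = float(value)
            except ValueError:
                raise DictionaryError(
                    f"{path}:{lineno}: degree value {value!r} is not a number"
                ) from None
        else:
            raise DictionaryError(f"{path}:{lineno}: unknown role {role!r}")
    return EmotionDictionary(entries=entries, negators=frozenset(negators),
                             degree_words=degree)
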