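"""Naranjo causality scoring, category bands, the study inclusion rule and
the seriousness flag.

The Naranjo questionnaire is ten items, each answered yes/no/unknown and
carrying a published weight per answer; the causality score is the sum of
the chosen weights. Score bands: definite >= 9, probable 5-8, possible 1-4,
doubtful <= 0. Only ADRs scoring >= 1 (possible or better) are included in
the unique-ADR sets the metrics count. The weight table is bundled as an
editable data file rather than hard-coded.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path
from typing import Sequence

from adrmine.lexicons import AdrTermIndex, LexiconError, bundled_path
from adrmine.miner import UniqueADR

__all__ = [
    "ANSWERS",
    "CATEGORIES",
    "NaranjoItem",
    "NaranjoAssessment",
    "load_weights",
    "score",
    "categorize",
    "include",
    "flag_serious",
    "score_range",
]

ANSWERS = ("yes", "no", "unknown")
CATEGORIES = ("doubtful", "possible", "probable", "definite")


@dataclass(frozen=True)
class NaranjoItem:
    item: int
    question: str
    yes: int
    no: int
    unknown: int

    def weight(self, answer: str) -> int:
        if answer not in ANSWERS:
            raise ValueError(f"answer must be one of {ANSWERS}, got {answer!r}")
        return getattr(self, answer)


@lru_cache(maxsize=None)
def _default_weights() -> tuple[NaranjoItem, ...]:
    return load_weights(bundled_path("naranjo_weights.tsv"))


def load_weights(path: str | Path) -> tuple[NaranjoItem, ...]:
    """Load the ten-item weight table (tab-separated: item, question, yes,
    no, unknown)."""
    items = []
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames != ["item", "question", "yes", "no", "unknown"]:
            raise ValueError(f"{path}: unexpected columns {reader.fieldnames}")
        for row in reader:
            items.append(
                NaranjoItem(
                    item=int(row["item"]),
                    question=row["question"],
                    yes=int(row["yes"]),
                    no=int(row["no"]),
                    unknown=int(row["unknown"]),
                )
            )
    if len(items) != 10:
        raise ValueError(f"{path}: expected 10 items, got {len(items)}")
    return tuple(items)


def score(answers: Sequence[str], weights: Sequence[NaranjoItem] | None = None) -> int:
    """Causality score: the weighted sum of exactly ten ternary answers."""
    weights = weights if weights is not None else _default_weights()
    if len(answers) != len(weights):
        raise ValueError(f"expected {len(weights)} answers, got {len(answers)}")
    return sum(item.weight(answer) for item, answer in zip(weights, answers))


def categorize(value: int) -> str:
    """Score band: definite >= 9, probable 5-8, possible 1-4, doubtful <= 0."""
    if value >= 9:
        return "definite"
    if value >= 5:
        return "probable"
    if value >= 1:
        return "possible"
    return "doubtful"


def include(value: int) -> bool:
    """Study inclusion rule: keep ADRs scoring possible or better (>= 1)."""
    return value >= 1


def score_range(weights: Sequence[NaranjoItem] | None = None) -> tuple[int, int]:
    """Reachable (min, max) score of a weight table."""
    weights = weights if weights is not None else _default_weights()
    lo = sum(min(i.yes, i.no, i.unknown) for i in weights)
    hi = sum(max(i.yes, i.no, i.unknown) for i in weights)
    return lo, hi


@dataclass(frozen=True)
class NaranjoAssessment:
    """A completed questionnaire with its derived score and category."""

    answers: tuple[str, ...]
    score: int
    category: str

    @classmethod
    def from_answers(
        cls, answers: Sequence[str], weights: Sequence[NaranjoItem] | None = None
    ) -> "NaranjoAssessment":
        s = score(answers, weights)
        return cls(answers=tuple(answers), score=s, category=categorize(s))


def flag_serious(unique_adr: UniqueADR, terms: AdrTermIndex) -> bool:
    """True iff the ADR's coded term is on the loaded serious-event (IME)
    list; an unresolvable code is a hard error."""
    if unique_adr.term_code not in terms:
        raise LexiconError(f"term code {unique_adr.term_code!r} not in dictionary")
    return terms[unique_adr.term_code].serious
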