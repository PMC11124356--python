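"""KIDMED Mediterranean-diet quality index for children and adolescents.

Sixteen yes/no items; a "yes" on an item aligned with the Mediterranean
dietary pattern scores +1, a "yes" on an item that undermines it scores
-1, and a "no" scores 0. Twelve items are positive and four negative, so
totals span -4..12 and fall into three adherence levels: >=8 optimal,
4-7 needs improvement, <=3 very low.

Item polarity is data: :func:`default_items` ships the original index
(fast food, skipped breakfast, commercial pastries for breakfast and
daily sweets as the four -1 items) but any published variant can be
loaded from an item table instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

__all__ = [
    "KidmedItem", "KidmedResponses", "KidmedScore",
    "default_items", "score_kidmed", "categorize_kidmed",
    "CATEGORIES",
]

CATEGORIES = ("optimal", "needs_improvement", "very_low")

SCORE_MIN, SCORE_MAX = -4, 12


@dataclass(frozen=True)
class KidmedItem:
    item_id: int
    description: str
    polarity: int  # +1 or -1

    def __post_init__(self) -> None:
        if self.polarity not in (+1, -1):
            raise ValueError(
                f"item {self.item_id}: polarity must be +1 or -1, got {self.polarity}"
            )
        if not 1 <= self.item_id <= 16:
            raise ValueError(f"item_id must be in 1..16, got {self.item_id}")


@dataclass(frozen=True)
class KidmedResponses:
    participant_id: str
    answers: Mapping[int, bool]  # item_id -> yes?


@dataclass(frozen=True)
class KidmedScore:
    score: int
    category: str
    complete: bool = True  # False when scored leniently with gaps

    def __post_init__(self) -> None:
        if not SCORE_MIN <= self.score <= SCORE_MAX:
            raise ValueError(f"score {self.score} outside [{SCORE_MIN}, {SCORE_MAX}]")
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")


_DEFAULT_ITEMS = (
    (1, "Takes a fruit or fruit juice every day", +1),
    (2, "Has a second fruit every day", +1),
    (3, "Has fresh or cooked vegetables regularly once a day", +1),
    (4, "Has fresh or cooked vegetables more than once a day", +1),
    (5, "Consumes fish regularly (at least 2-3 times per week)", +1),
    (6, "Goes more than once a week to a fast-food restaurant", -1),
    (7, "Likes pulses and eats them more than once a week", +1),
    (8, "Consumes pasta or rice almost every day (5 or more per week)", +1),
    (9, "Has cereals or grains (bread, etc.) for breakfast", +1),
    (10, "Consumes nuts regularly (at least 2-3 times per week)", +1),
    (11, "Uses olive oil at home", +1),
    (12, "Skips breakfast", -1),
    (13, "Has a dairy product for breakfast (yoghurt, milk, etc.)", +1),
    (14, "Has commercially baked goods or pastries for breakfast", -1),
    (15, "Takes two yoghurts and/or some cheese (40 g) daily", +1),
    (16, "Takes sweets and candy several times every day", -1),
)


def default_items() -> list[KidmedItem]:
    """The 16 items of the original index (12 positive, 4 negative)."""
    return [KidmedItem(i, d, p) for i, d, p in _DEFAULT_ITEMS]


def _validate_items(items: list[KidmedItem]) -> None:
    ids = [it.item_id for it in items]
    if len(items) != 16 or sorted(ids) != list(range(1, 17)):
        raise ValueError(
            f"a questionnaire needs items 1..16 exactly once, got ids {sorted(ids)}"
        )
    n_neg = sum(1 for it in items if it.polarity == -1)
    if n_neg != 4:
        raise ValueError(
            f"expected 4 negative and 12 positive items (score range -4..12), "
            f"got {n_neg} negative"
        )


def categorize_kidmed(score: int) -> str:
    """Adherence level for a total score: >=8 optimal, 4-7 needs
    improvement, <=3 very low."""
    if not SCORE_MIN <= score <= SCORE_MAX:
        raise ValueError(f"score {score} outside attainable range [{SCORE_MIN}, {SCORE_MAX}]")
    if score >= 8:
        return "optimal"
    if score >= 4:
        return "needs_improvement"
    return "very_low"


def score_kidmed(
    responses: KidmedResponses,
    items: list[KidmedItem] | None = None,
    *,
    lenient: bool = False,
) -> KidmedScore:
    """Total score and adherence category for one participant.

    Every item must be answered; with ``lenient=True`` missing items
    score 0 and the result is flagged ``complete=False``. Extra answers
    for unknown item ids are always rejected.
    """
    items = default_items() if items is None else items
    _validate_items(items)
    known = {it.item_id for it in items}
    answered = set(responses.answers)
    extra = sorted(answered - known)
    if extra:
        raise ValueError(
            f"participant {responses.participant_id!r}: answers for unknown items {extra}"
        )
    missing = sorted(known - answered)
    if missing and not lenient:
        raise ValueError(
            f"participant {responses.participant_id!r}: missing answers for items {missing}"
        )
    score = sum(
        it.polarity
        for it in items
        if responses.answers.get(it.item_id, False)
    )
    return KidmedScore(
        score=score,
        category=categorize_kidmed(score),
        complete=not missing,
    )
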