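"""Composite physical-performance scores and the FOSTA comparator.

Scores derived here:

* two-step test (TST): maximum two-stride distance / body height, unitless;
* stand-up test: ordinal 1-8 for the hardest box-rise task completed
  (both legs 40/30/20/10 cm, then one leg 40/30/20/10 cm);
* Locomo25: sum of 25 items each graded 0-4, total 0-100 (higher = worse);
* FOSTA: the weight-and-age self-assessment score for Asian women,
  truncate(0.2 * (weight - age)), with < -4 flagging high osteoporosis risk.
  The FOSTA formula is external to this analysis and included only as a
  comparator.

Side-averaging of grip and knee-extension happens at data ingest, not here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

from .cohort import ValidationError

__all__ = [
    "StandupTask",
    "STANDUP_TASKS",
    "FostaResult",
    "tst_score",
    "standup_points",
    "locomo25_total",
    "fosta_score",
]

_BOX_HEIGHTS = (40, 30, 20, 10)
_LEGS = ("both", "one")


@dataclass(frozen=True, order=False)
class StandupTask:
    """One box-rise task: legs in {'both', 'one'}, box_height in {40,30,20,10} cm."""

    legs: str
    box_height: int

    def __post_init__(self) -> None:
        if self.legs not in _LEGS:
            raise ValidationError(f"legs must be 'both' or 'one', got {self.legs!r}")
        if self.box_height not in _BOX_HEIGHTS:
            raise ValidationError(f"box_height must be one of {_BOX_HEIGHTS}, got {self.box_height}")


#: All eight tasks in difficulty order (easiest first).
STANDUP_TASKS = tuple(
    StandupTask(legs=legs, box_height=h) for legs in _LEGS for h in _BOX_HEIGHTS
)


def tst_score(two_step_distance: float, height: float) -> float:
    """Two-step test: distance [cm] divided by body height [cm]."""
    if not (two_step_distance > 0 and height > 0):
        raise ValidationError(
            f"distance and height must be positive, got {two_step_distance}, {height}"
        )
    return two_step_distance / height


def standup_points(hardest_completed: StandupTask) -> int:
    """Points 1-8: rank of the hardest completed task in the difficulty order."""
    return STANDUP_TASKS.index(hardest_completed) + 1


def locomo25_total(items: Sequence[int]) -> int:
    """Total Locomo25 score: sum of exactly 25 items, each an integer 0-4."""
    items = list(items)
    if len(items) != 25:
        raise ValidationError(f"Locomo25 requires exactly 25 items, got {len(items)}")
    for i, v in enumerate(items):
        if not (isinstance(v, int) and 0 <= v <= 4):
            raise ValidationError(f"item {i + 1} must be an integer in 0-4, got {v!r}")
    return sum(items)


class FostaResult(NamedTuple):
    score: int
    high_risk: bool


def fosta_score(weight: float, age: float) -> FostaResult:
    """FOSTA score truncate(0.2 * (weight - age)); high risk when score < -4."""
    if not (weight > 0 and age > 0):
        raise ValidationError(f"weight and age must be positive, got {weight}, {age}")
    raw = 0.2 * (weight - age)
    score = math.trunc(raw)
    return FostaResult(score=score, high_risk=score < -4)
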