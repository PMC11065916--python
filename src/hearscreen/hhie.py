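"""Scoring of the Hearing Handicap Inventory for the Elderly, screening
version (HHIE-s).

Ten items (five emotional, five situational by positional convention:
items 1-5 emotional, 6-10 situational), each answered yes / sometimes /
never, worth 4 / 2 / 0 points.  Totals are therefore even and range 0-40.
Bands: 0-8 no obvious handicap, 10-22 mild-to-moderate, 24-40 severe; the
abnormality flag used by the triage rules is total >= 10.

An odd total (e.g. 9) is unreachable under the scoring weights, so odd
inputs are rejected as corrupted data rather than rounded into a band.
"""

from __future__ import annotations

import enum
from typing import Sequence

from pydantic import BaseModel, ConfigDict, field_validator, model_validator

__all__ = [
    "Response",
    "Category",
    "HHIEResponses",
    "HHIEResult",
    "score_hhie",
    "categorize_hhie",
    "evaluate_hhie",
    "N_ITEMS",
    "MAX_SCORE",
    "ABNORMAL_CUTOFF",
]

N_ITEMS = 10
MAX_SCORE = 40
#: total >= 10 flags a hearing handicap in the triage rules
ABNORMAL_CUTOFF = 10

_POINTS = {"yes": 4, "sometimes": 2, "never": 0}


class Response(str, enum.Enum):
    yes = "yes"
    sometimes = "sometimes"
    never = "never"


class Category(str, enum.Enum):
    no_obvious = "no_obvious"
    mild_moderate = "mild_moderate"
    severe = "severe"


class HHIEResponses(BaseModel):
    model_config = ConfigDict(frozen=True)

    items: tuple[Response, ...]

    @field_validator("items")
    @classmethod
    def _ten_items(cls, v: tuple[Response, ...]) -> tuple[Response, ...]:
        if len(v) != N_ITEMS:
            raise ValueError(f"expected exactly {N_ITEMS} items, got {len(v)}")
        return v

    @property
    def emotional(self) -> tuple[Response, ...]:
        return self.items[:5]

    @property
    def situational(self) -> tuple[Response, ...]:
        return self.items[5:]


class HHIEResult(BaseModel):
    model_config = ConfigDict(frozen=True)

    total: int
    category: Category
    abnormal: bool

    @model_validator(mode="after")
    def _check(self) -> "HHIEResult":
        cat, abn = categorize_hhie(self.total)
        if (cat, abn) != (self.category, self.abnormal):
            raise ValueError(
                f"category/abnormal inconsistent with total {self.total}"
            )
        return self


def score_hhie(responses: HHIEResponses | Sequence[Response | str]) -> int:
    """Total score: 4 points per 'yes', 2 per 'sometimes', 0 per 'never'."""
    if not isinstance(responses, HHIEResponses):
        responses = HHIEResponses(items=tuple(responses))
    return sum(_POINTS[item.value] for item in responses.items)


def categorize_hhie(total: int) -> tuple[Category, bool]:
    """Band a total into its handicap category and abnormality flag.

    Raises on odd or out-of-range totals: they cannot arise from valid
    responses, so they indicate corrupted input.
    """
    if not 0 <= total <= MAX_SCORE:
        raise ValueError(f"total must be in [0, {MAX_SCORE}], got {total}")
    if total % 2:
        raise ValueError(
            f"total must be even (items score 4/2/0), got {total}"
        )
    if total <= 8:
        return Category.no_obvious, False
    if total <= 22:
        return Category.mild_moderate, True
    return Category.severe, True


def evaluate_hhie(responses: HHIEResponses | Sequence[Response | str]) -> HHIEResult:
    """Score and band in one call."""
    total = score_hhie(responses)
    category, abnormal = categorize_hhie(total)
    return HHIEResult(total=total, category=category, abnormal=abnormal)
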