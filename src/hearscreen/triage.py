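"""Combination of the three screen components into a conclusion and a
re-screening recommendation.

A subject is screen-positive if *any* component flags them: high risk
stratum, abnormal HHIE-s (total >= 10), or failed two-step audiometry.
Screen-negative subjects are advised to re-screen every 6 months,
screen-positive subjects every 3 months; a failed audiometry additionally
triggers referral to the general practitioner, since it indicates probable
moderate-or-worse loss rather than elevated risk alone.

The all-negative and all-positive corner cases are fixed by the tool's
stated advice; mixed patterns follow the any-positive (OR) rule — the only
combination consistent with the tool's validated 100% sensitivity and 100%
negative predictive value, and the one that maximises screening
sensitivity, the purpose of a community screen.
"""

from __future__ import annotations

from typing import Iterable, List

from pydantic import BaseModel, ConfigDict, model_validator

from .risk import Stratum

__all__ = ["ScreeningConclusion", "conclude", "screen_positive_batch"]

INTERVAL_NEGATIVE_MONTHS = 6
INTERVAL_POSITIVE_MONTHS = 3


class ScreeningConclusion(BaseModel):
    model_config = ConfigDict(frozen=True)

    risk_stratum: Stratum
    hhie_abnormal: bool
    audiometry_failed: bool
    screen_positive: bool
    rescreen_interval_months: int
    refer_to_gp: bool

    @model_validator(mode="after")
    def _check(self) -> "ScreeningConclusion":
        any_flag = (
            self.risk_stratum is Stratum.high
            or self.hhie_abnormal
            or self.audiometry_failed
        )
        if self.screen_positive != any_flag:
            raise ValueError("screen_positive must equal the OR of component flags")
        expect_interval = (
            INTERVAL_POSITIVE_MONTHS if self.screen_positive else INTERVAL_NEGATIVE_MONTHS
        )
        if self.rescreen_interval_months != expect_interval:
            raise ValueError(
                f"rescreen interval {self.rescreen_interval_months} inconsistent "
                f"with screen_positive={self.screen_positive}"
            )
        if self.refer_to_gp != self.audiometry_failed:
            raise ValueError("refer_to_gp must mirror audiometry_failed")
        return self


def conclude(
    risk_stratum: Stratum,
    hhie_abnormal: bool,
    audiometry_failed: bool,
) -> ScreeningConclusion:
    """Build the conclusion for one subject from the three component results."""
    positive = risk_stratum is Stratum.high or hhie_abnormal or audiometry_failed
    return ScreeningConclusion(
        risk_stratum=risk_stratum,
        hhie_abnormal=hhie_abnormal,
        audiometry_failed=audiometry_failed,
        screen_positive=positive,
        rescreen_interval_months=(
            INTERVAL_POSITIVE_MONTHS if positive else INTERVAL_NEGATIVE_MONTHS
        ),
        refer_to_gp=audiometry_failed,
    )


def screen_positive_batch(conclusions: Iterable[ScreeningConclusion]) -> List[bool]:
    """Element-wise screen_positive flags, order-preserving."""
    return [c.screen_positive for c in conclusions]
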