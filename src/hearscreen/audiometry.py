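"""Two-step two-tone screening audiometry and the pure-tone-audiometry
(PTA) reference classification.

The screen plays a 2 kHz tone at 42 dB HL twice; a subject who fails to
hear it both times is flagged (moderate-or-worse loss) without further
testing.  Hearing it twice triggers a 0.5 kHz tone at 47 dB HL, again
twice; failing that step likewise flags the ear.  Only an ear that hears
both tones on both presentations passes.  Both ears are tested; the screen
as a whole passes if *either* ear passes, because the reference standard is
the better-ear PTA average, so the screen targets the better ear.

The reference standard is the arithmetic mean of air-conduction thresholds
at 0.5, 1, 2 and 4 kHz in the better ear, graded as

    normal <= 25 < mild <= 40 < moderate <= 55 < moderately severe <= 70
    < severe <= 90 < profound.

Band edges are compared without rounding, so non-integer averages (25.25
dB) fall unambiguously into a band; the two binary reference targets are
hearing loss (> 25 dB HL) and moderate-or-worse loss (> 40 dB HL).
"""

from __future__ import annotations

import enum
from typing import Mapping, Optional, Sequence

from pydantic import BaseModel, ConfigDict, model_validator

__all__ = [
    "FREQUENCIES_HZ",
    "TONE_2K_LEVEL_DB",
    "TONE_500_LEVEL_DB",
    "EarResult",
    "Grade",
    "EarTrial",
    "AudiometryScreenResult",
    "PTARecord",
    "two_step_ear",
    "two_step_binaural",
    "pta_classify",
    "grade_for_average",
]

#: PTA frequencies entering the better-ear average, in Hz.
FREQUENCIES_HZ: tuple[int, ...] = (500, 1000, 2000, 4000)

#: Screening tone presentation levels, dB HL.
TONE_2K_LEVEL_DB = 42.0
TONE_500_LEVEL_DB = 47.0

_THRESHOLD_MIN, _THRESHOLD_MAX = -10.0, 120.0


class EarResult(str, enum.Enum):
    passed = "passed"
    failed = "failed"


class Grade(str, enum.Enum):
    normal = "normal"
    mild = "mild"
    moderate = "moderate"
    moderately_severe = "moderately_severe"
    severe = "severe"
    profound = "profound"


#: (upper edge inclusive, grade), scanned in order; profound is open-ended.
_GRADE_EDGES: tuple[tuple[float, Grade], ...] = (
    (25.0, Grade.normal),
    (40.0, Grade.mild),
    (55.0, Grade.moderate),
    (70.0, Grade.moderately_severe),
    (90.0, Grade.severe),
)


class EarTrial(BaseModel):
    """Perception counts for one ear's tone presentations.

    ``heard_500`` may only be present when the 2 kHz step was passed
    (heard twice): the second tone is never administered otherwise.
    """

    model_config = ConfigDict(frozen=True)

    heard_2k: int
    heard_500: Optional[int] = None

    @model_validator(mode="after")
    def _check(self) -> "EarTrial":
        if self.heard_2k not in (0, 1, 2):
            raise ValueError(f"heard_2k must be 0, 1 or 2, got {self.heard_2k}")
        if self.heard_500 is not None:
            if self.heard_500 not in (0, 1, 2):
                raise ValueError(
                    f"heard_500 must be 0, 1 or 2, got {self.heard_500}"
                )
            if self.heard_2k != 2:
                raise ValueError(
                    "heard_500 present although the 2 kHz step was not passed "
                    f"(heard_2k={self.heard_2k}); the 0.5 kHz tone is only "
                    "administered after hearing the 2 kHz tone twice"
                )
        return self


class AudiometryScreenResult(BaseModel):
    model_config = ConfigDict(frozen=True)

    left: EarResult
    right: EarResult
    overall: EarResult

    @model_validator(mode="after")
    def _check(self) -> "AudiometryScreenResult":
        either = EarResult.passed in (self.left, self.right)
        if (self.overall is EarResult.passed) != either:
            raise ValueError("overall must be passed iff at least one ear passed")
        return self


class PTARecord(BaseModel):
    """Reference pure-tone thresholds and their derived classification."""

    model_config = ConfigDict(frozen=True)

    left: tuple[float, float, float, float]
    right: tuple[float, float, float, float]
    better_ear_avg: float
    grade: Grade
    hearing_loss: bool
    moderate_or_worse: bool


def two_step_ear(trial: EarTrial) -> EarResult:
    """Decision tree for one ear.

    Fails immediately if the 2 kHz tone was heard fewer than two times
    (the 0.5 kHz count is never consulted in that case); otherwise fails
    if the 0.5 kHz tone was heard fewer than two times; otherwise passes.
    """
    if trial.heard_2k < 2:
        return EarResult.failed
    if trial.heard_500 is None:
        raise ValueError(
            "2 kHz step passed but no 0.5 kHz trial recorded; the second "
            "tone must be administered after the first is heard twice"
        )
    return EarResult.passed if trial.heard_500 == 2 else EarResult.failed


def two_step_binaural(left: EarTrial, right: EarTrial) -> AudiometryScreenResult:
    """Apply the decision tree per ear; the screen passes iff either ear passes."""
    lres = two_step_ear(left)
    rres = two_step_ear(right)
    overall = (
        EarResult.passed
        if EarResult.passed in (lres, rres)
        else EarResult.failed
    )
    return AudiometryScreenResult(left=lres, right=rres, overall=overall)


def grade_for_average(avg: float) -> Grade:
    """Grade band containing a 4-frequency average (no rounding at edges)."""
    for edge, grade in _GRADE_EDGES:
        if avg <= edge:
            return grade
    return Grade.profound


def _coerce_thresholds(
    ear: Sequence[float] | Mapping[int, float], side: str
) -> tuple[float, float, float, float]:
    if isinstance(ear, Mapping):
        missing = [f for f in FREQUENCIES_HZ if f not in ear]
        if missing:
            raise ValueError(f"{side} ear missing threshold at {missing} Hz")
        vals = tuple(float(ear[f]) for f in FREQUENCIES_HZ)
    else:
        vals = tuple(float(v) for v in ear)
        if len(vals) != 4:
            raise ValueError(
                f"{side} ear needs 4 thresholds (0.5/1/2/4 kHz), got {len(vals)}"
            )
    for f, v in zip(FREQUENCIES_HZ, vals):
        if not _THRESHOLD_MIN <= v <= _THRESHOLD_MAX:
            raise ValueError(
                f"{side} ear {f} Hz threshold {v} dB HL outside plausible "
                f"range [{_THRESHOLD_MIN}, {_THRESHOLD_MAX}]"
            )
    return vals  # type: ignore[return-value]


def pta_classify(
    left: Sequence[float] | Mapping[int, float],
    right: Sequence[float] | Mapping[int, float],
) -> PTARecord:
    """Classify per-ear thresholds into the reference-standard record.

    Each ear supplies thresholds at 0.5, 1, 2 and 4 kHz (sequence in that
    order, or a mapping keyed by Hz).  The better-ear average is the lower
    of the two ears' arithmetic means.
    """
    lvals = _coerce_thresholds(left, "left")
    rvals = _coerce_thresholds(right, "right")
    better = min(sum(lvals) / 4.0, sum(rvals) / 4.0)
    return PTARecord(
        left=lvals,
        right=rvals,
        better_ear_avg=better,
        grade=grade_for_average(better),
        hearing_loss=better > 25.0,
        moderate_or_worse=better > 40.0,
    )
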