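"""Risk-factor derivation, cumulative scoring and high/low stratification.

Age-related hearing loss (ARHL) screening starts from a cumulative count of
18 binary risk indicators derived from a subject's demographic, lifestyle
and chronic-disease profile.  The count is dichotomised at an operational
threshold (default 4) into low-risk (< threshold) and high-risk
(>= threshold) strata.

Age is deliberately *not* a score factor: the screened population is already
restricted to adults aged 60 and over, so age carries no discriminative
weight within the score (it does, however, enter the generative model of the
cohort simulator).  A history of chronic otitis media is collected on the
profile but is likewise not among the 18 indicators.
"""

from __future__ import annotations

import enum
from typing import Optional

from pydantic import BaseModel, ConfigDict, model_validator

__all__ = [
    "FACTOR_NAMES",
    "Sex",
    "MaritalStatus",
    "Diet",
    "Stratum",
    "SubjectProfile",
    "RiskFactorVector",
    "RiskAssessment",
    "derive_risk_factors",
    "cumulative_score",
    "stratify",
    "DEFAULT_THRESHOLD",
]

#: Canonical order of the 18 binary risk indicators.  This order is a
#: documented part of the data contract: it fixes CSV column order and the
#: layout of the simulator's coefficient vector.
FACTOR_NAMES: tuple[str, ...] = (
    "male",
    "overweight_obesity",
    "living_alone",
    "widowed_divorced",
    "noise_history",
    "family_deafness",
    "non_light_diet",
    "no_exercise",
    "smoking",
    "drinking",
    "headset_habit",
    "hypertension",
    "diabetes",
    "hyperlipidemia",
    "cardio_cerebrovascular",
    "hyperuricemia",
    "hypothyroidism",
    "ototoxic_drugs",
)

#: BMI at or above this value counts as the overweight/obesity indicator.
BMI_OVERWEIGHT_CUTOFF = 24.0

#: Default operational threshold: score >= 4 is high risk.
DEFAULT_THRESHOLD = 4


class Sex(str, enum.Enum):
    male = "male"
    female = "female"


class MaritalStatus(str, enum.Enum):
    married = "married"
    widowed = "widowed"
    divorced = "divorced"


class Diet(str, enum.Enum):
    light = "light"
    non_light = "non_light"


class Stratum(str, enum.Enum):
    low = "low"
    high = "high"


class SubjectProfile(BaseModel):
    """Raw per-subject fields from which the risk indicators are derived.

    Behavioural exposures (smoking, drinking, noise, headset use) arrive as
    pre-resolved booleans: the questionnaire front-end applies the duration
    arithmetic of their operational definitions (e.g. smoking more than one
    cigarette per day for six cumulative months), so this module never sees
    raw durations.

    ``bmi`` may be omitted when both ``height`` (cm) and ``weight`` (kg) are
    given; it is then derived as weight / (height in m)^2.
    """

    model_config = ConfigDict(frozen=True)

    subject_id: str
    age: int
    sex: Sex
    height: Optional[float] = None
    weight: Optional[float] = None
    bmi: Optional[float] = None
    lives_alone: bool
    marital_status: MaritalStatus
    noise_history: bool
    family_deafness: bool
    diet: Diet
    exercise_habit: bool
    smoking: bool
    drinking: bool
    headset_habit: bool
    hypertension: bool
    diabetes: bool
    hyperlipidemia: bool
    cardio_cerebrovascular: bool
    hyperuricemia: bool
    hypothyroidism: bool
    ototoxic_drug_history: bool
    chronic_otitis_media: bool = False

    @model_validator(mode="after")
    def _check(self) -> "SubjectProfile":
        if self.age < 60:
            raise ValueError(f"age must be >= 60 years, got {self.age}")
        if self.bmi is None:
            if self.height is None or self.weight is None:
                raise ValueError(
                    "bmi missing and not derivable: both height and weight required"
                )
            if self.height <= 0:
                raise ValueError(f"height must be positive, got {self.height}")
            if self.weight <= 0:
                raise ValueError(f"weight must be positive, got {self.weight}")
        elif self.bmi <= 0:
            raise ValueError(f"bmi must be positive, got {self.bmi}")
        return self

    @property
    def bmi_value(self) -> float:
        """BMI in kg/m^2, derived from height/weight when not given directly."""
        if self.bmi is not None:
            return self.bmi
        assert self.height is not None and self.weight is not None
        return self.weight / (self.height / 100.0) ** 2


class RiskFactorVector(BaseModel):
    """The 18 binary indicators, one boolean field per canonical factor."""

    model_config = ConfigDict(frozen=True)

    male: bool
    overweight_obesity: bool
    living_alone: bool
    widowed_divorced: bool
    noise_history: bool
    family_deafness: bool
    non_light_diet: bool
    no_exercise: bool
    smoking: bool
    drinking: bool
    headset_habit: bool
    hypertension: bool
    diabetes: bool
    hyperlipidemia: bool
    cardio_cerebrovascular: bool
    hyperuricemia: bool
    hypothyroidism: bool
    ototoxic_drugs: bool

    def as_tuple(self) -> tuple[bool, ...]:
        """Indicator values in canonical :data:`FACTOR_NAMES` order."""
        return tuple(getattr(self, name) for name in FACTOR_NAMES)


# the vector type and the canonical name list must never drift apart
assert set(RiskFactorVector.model_fields) == set(FACTOR_NAMES)


class RiskAssessment(BaseModel):
    model_config = ConfigDict(frozen=True)

    score: int
    threshold: int = DEFAULT_THRESHOLD
    stratum: Stratum

    @model_validator(mode="after")
    def _check(self) -> "RiskAssessment":
        if not 0 <= self.score <= len(FACTOR_NAMES):
            raise ValueError(f"score must be in [0, 18], got {self.score}")
        if self.threshold < 1:
            raise ValueError(f"threshold must be >= 1, got {self.threshold}")
        expect = Stratum.high if self.score >= self.threshold else Stratum.low
        if self.stratum != expect:
            raise ValueError(
                f"stratum {self.stratum.value!r} inconsistent with "
                f"score {self.score} at threshold {self.threshold}"
            )
        return self


def derive_risk_factors(profile: SubjectProfile) -> RiskFactorVector:
    """Map a validated profile to its 18 binary risk indicators.

    Operational definitions: overweight/obesity is BMI >= 24.0 kg/m^2
    (boundary inclusive); widowed/divorced is any non-married status;
    no-exercise is the negation of a regular exercise habit; all remaining
    indicators are copied from the like-named boolean profile fields.
    """
    return RiskFactorVector(
        male=profile.sex is Sex.male,
        overweight_obesity=profile.bmi_value >= BMI_OVERWEIGHT_CUTOFF,
        living_alone=profile.lives_alone,
        widowed_divorced=profile.marital_status
        in (MaritalStatus.widowed, MaritalStatus.divorced),
        noise_history=profile.noise_history,
        family_deafness=profile.family_deafness,
        non_light_diet=profile.diet is Diet.non_light,
        no_exercise=not profile.exercise_habit,
        smoking=profile.smoking,
        drinking=profile.drinking,
        headset_habit=profile.headset_habit,
        hypertension=profile.hypertension,
        diabetes=profile.diabetes,
        hyperlipidemia=profile.hyperlipidemia,
        cardio_cerebrovascular=profile.cardio_cerebrovascular,
        hyperuricemia=profile.hyperuricemia,
        hypothyroidism=profile.hypothyroidism,
        ototoxic_drugs=profile.ototoxic_drug_history,
    )


def cumulative_score(vector: RiskFactorVector) -> int:
    """Count of indicators set, the cumulative risk score in [0, 18]."""
    return sum(vector.as_tuple())


def stratify(score: int, threshold: int = DEFAULT_THRESHOLD) -> Stratum:
    """Dichotomise a cumulative score: high iff ``score >= threshold``."""
    if score < 0:
        raise ValueError(f"score must be non-negative, got {score}")
    if score > len(FACTOR_NAMES):
        raise ValueError(f"score must be <= 18, got {score}")
    if threshold < 1:
        raise ValueError(f"threshold must be >= 1, got {threshold}")
    return Stratum.high if score >= threshold else Stratum.low


def assess(profile: SubjectProfile, threshold: int = DEFAULT_THRESHOLD) -> RiskAssessment:
    """Convenience: derive factors, score and stratify in one call."""
    score = cumulative_score(derive_risk_factors(profile))
    return RiskAssessment(score=score, threshold=threshold, stratum=stratify(score, threshold))


def factor_matrix(subjects) -> "pandas.DataFrame":  # noqa: F821
    """Vectorised :func:`derive_risk_factors` over a subjects DataFrame.

    Applies the same operational definitions column-wise and returns a 0/1
    frame with the 18 canonical factor columns in order.  Requires a `bmi`
    column or both `height` and `weight`.
    """
    import numpy as np
    import pandas as pd

    if "bmi" in subjects.columns and subjects["bmi"].notna().all():
        bmi = subjects["bmi"].astype(float)
    else:
        bmi = subjects["weight"].astype(float) / (
            subjects["height"].astype(float) / 100.0
        ) ** 2
    out = pd.DataFrame(index=subjects.index)
    out["male"] = subjects["sex"].astype(str).str.lower().eq("male")
    out["overweight_obesity"] = bmi >= BMI_OVERWEIGHT_CUTOFF
    out["living_alone"] = subjects["lives_alone"].astype(int).astype(bool)
    out["widowed_divorced"] = (
        subjects["marital_status"].astype(str).str.lower().isin(["widowed", "divorced"])
    )
    out["noise_history"] = subjects["noise_history"].astype(int).astype(bool)
    out["family_deafness"] = subjects["family_deafness"].astype(int).astype(bool)
    out["non_light_diet"] = subjects["diet"].astype(str).str.lower().eq("non_light")
    out["no_exercise"] = ~subjects["exercise_habit"].astype(int).astype(bool)
    for col in ("smoking", "drinking", "headset_habit", "hypertension", "diabetes",
                "hyperlipidemia", "cardio_cerebrovascular", "hyperuricemia",
                "hypothyroidism"):
        out[col] = subjects[col].astype(int).astype(bool)
    out["ototoxic_drugs"] = subjects["ototoxic_drug_history"].astype(int).astype(bool)
    assert list(out.columns) == list(FACTOR_NAMES)
    return out.astype(np.int8)
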