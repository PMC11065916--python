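import pytest

from hearscreen.risk import SubjectProfile
from hearscreen.simulate import CohortParams, simulate_cohort


@pytest.fixture
def negative_profile_kwargs():
    """A profile with every exposure/disease flag negative and BMI < 24."""
    return dict(
        subject_id="P001",
        age=65,
        sex="female",
        bmi=22.0,
        lives_alone=False,
        marital_status="married",
        noise_history=False,
        family_deafness=False,
        diet="light",
        exercise_habit=True,
        smoking=False,
        drinking=False,
        headset_habit=False,
        hypertension=False,
        diabetes=False,
        hyperlipidemia=False,
        cardio_cerebrovascular=False,
        hyperuricemia=False,
        hypothyroidism=False,
        ototoxic_drug_history=False,
    )


@pytest.fixture
def negative_profile(negative_profile_kwargs):
    return SubjectProfile(**negative_profile_kwargs)


@pytest.fixture(scope="session")
def default_cohort_2000():
    """One moderately sized default-parameter cohort, shared across tests."""
    return simulate_cohort(CohortParams(n=2000, seed=1234))
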