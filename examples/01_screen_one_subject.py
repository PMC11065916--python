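"""Screen a single subject through all three components.

Builds one profile by hand, scores the 18 risk factors, the HHIE-s
questionnaire and the two-step tone test, and prints the triage
conclusion.
"""

from hearscreen import (
    EarTrial,
    SubjectProfile,
    assess,
    conclude,
    evaluate_hhie,
    two_step_binaural,
)
from hearscreen.audiometry import EarResult

profile = SubjectProfile(
    subject_id="demo-001",
    age=72,
    sex="male",
    height=168.0,
    weight=74.0,  # BMI 26.2 -> overweight/obesity indicator set
    lives_alone=False,
    marital_status="married",
    noise_history=True,  # >1 year in >85 dB occupational noise
    family_deafness=False,
    diet="non_light",
    exercise_habit=True,
    smoking=False,
    drinking=False,
    headset_habit=False,
    hypertension=True,
    diabetes=False,
    hyperlipidemia=False,
    cardio_cerebrovascular=False,
    hyperuricemia=False,
    hypothyroidism=False,
    ototoxic_drug_history=False,
)

risk = assess(profile)  # default threshold: score >= 4 is high risk

# answers to the 10 HHIE-s items (5 emotional, then 5 situational)
hhie = evaluate_hhie(
    ["sometimes", "never", "yes", "never", "never",
     "sometimes", "never", "never", "sometimes", "never"]
)

# heard the 2 kHz 42 dB tone twice in each ear, then the 0.5 kHz 47 dB tone
audio = two_step_binaural(
    EarTrial(heard_2k=2, heard_500=2),   # left: passed both steps
    EarTrial(heard_2k=1),                # right: failed the first step
)

conclusion = conclude(
    risk.stratum, hhie.abnormal, audio.overall is EarResult.failed
)

print(f"risk score        : {risk.score}/18 -> {risk.stratum.value} risk")
print(f"HHIE-s total      : {hhie.total}/40 -> {hhie.category.value}"
      f" (abnormal: {hhie.abnormal})")
print(f"audiometry        : left {audio.left.value}, right {audio.right.value}"
      f" -> overall {audio.overall.value}")
print(f"screen positive   : {conclusion.screen_positive}")
print(f"re-screen advised : every {conclusion.rescreen_interval_months} months")
print(f"refer to GP       : {conclusion.refer_to_gp}")
# A high risk score OR an abnormal HHIE-s OR a failed tone test makes the
# screen positive (3-month re-screen); only a failed tone test - probable
# moderate-or-worse loss - triggers GP referral.
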