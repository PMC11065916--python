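"""Cohort generator: determinism, calibration, structure and monotone
severity of the downstream signals."""

import math

import numpy as np
import pandas as pd
import pytest

from hearscreen.audiometry import EarResult, two_step_binaural
from hearscreen.hhie import score_hhie
from hearscreen.simulate import (
    CohortParams,
    DEFAULT_GRADE_MIX,
    calibrate_intercept,
    protocol_operating_characteristics,
    simulate_cohort,
)

GRADE_ORDER = ["normal", "mild", "moderate", "moderately_severe", "severe", "profound"]


class TestCalibrateIntercept:
    def test_all_zero_coefficients_give_logit_target(self):
        p = CohortParams(n=10, seed=0, coefficients={}, target_prevalence=0.5)
        assert calibrate_intercept(p) == pytest.approx(0.0)
        p = CohortParams(n=10, seed=0, coefficients={}, target_prevalence=0.798)
        assert calibrate_intercept(p) == pytest.approx(math.log(0.798 / 0.202))

    def test_unattainable_target_rejected(self):
        with pytest.raises(Exception):
            CohortParams(n=10, seed=0, target_prevalence=1.0)


class TestDeterminism:
    def test_same_params_same_seed_bitwise_identical(self):
        a = simulate_cohort(CohortParams(n=300, seed=9))
        b = simulate_cohort(CohortParams(n=300, seed=9))
        pd.testing.assert_frame_equal(a.subjects, b.subjects)
        pd.testing.assert_frame_equal(a.truth, b.truth)
        assert a.intercept == b.intercept

    def test_different_seeds_differ(self):
        a = simulate_cohort(CohortParams(n=300, seed=9))
        b = simulate_cohort(CohortParams(n=300, seed=10))
        assert not a.subjects.equals(b.subjects)


class TestStructure:
    def test_every_subject_passes_downstream_validation(self, default_cohort_2000):
        count = 0
        for sub in default_cohort_2000.profiles():
            # latent indicator consistent with the PTA grade
            assert sub.hearing_loss == (sub.pta.grade.value != "normal")
            assert sub.hearing_loss == sub.pta.hearing_loss
            count += 1
            if count >= 500:
                break
        assert count == 500

    def test_grade_mix_roughly_matches_configuration(self, default_cohort_2000):
        truth = default_cohort_2000.truth
        loss = truth[truth.hearing_loss == 1]
        mix = loss.grade.value_counts(normalize=True)
        expected = {g: v / sum(DEFAULT_GRADE_MIX.values())
                    for g, v in DEFAULT_GRADE_MIX.items()}
        for grade, frac in expected.items():
            if frac >= 0.05:
                se = math.sqrt(frac * (1 - frac) / len(loss))
                assert abs(mix.get(grade, 0.0) - frac) < 4 * se

    def test_ages_truncated_at_minimum(self, default_cohort_2000):
        assert (default_cohort_2000.subjects.age >= 60).all()

    def test_noiseless_mode_low_thresholds_always_pass(self):
        p = CohortParams(n=200, seed=2, tone_slope=0.0)
        cohort = simulate_cohort(p)
        s = cohort.subjects
        # in noiseless mode perception is a step at the true threshold:
        # an ear whose 2 kHz threshold <= 42 and 0.5 kHz threshold <= 47 passes
        for side in ("left", "right"):
            audible = (s[f"pta_{side}_2000"] <= 42.0) & (s[f"pta_{side}_500"] <= 47.0)
            heard_both = (s[f"heard_2k_{side}"] == 2) & (s[f"heard_500_{side}"] == 2)
            assert (audible == heard_both).all()

    def test_thresholds_mean_reproduces_better_ear_average(self, default_cohort_2000):
        s = default_cohort_2000.subjects
        t = default_cohort_2000.truth
        left = s[[f"pta_left_{f}" for f in (500, 1000, 2000, 4000)]].mean(axis=1)
        right = s[[f"pta_right_{f}" for f in (500, 1000, 2000, 4000)]].mean(axis=1)
        better = np.minimum(left, right)
        assert np.allclose(better, t.better_ear_avg, atol=0.2)


class TestMonotoneSeverity:
    def test_hhie_total_and_audiometry_failure_rise_with_grade(self, default_cohort_2000):
        s = default_cohort_2000.subjects
        t = default_cohort_2000.truth
        hhie_cols = [f"hhie_q{i}" for i in range(1, 11)]
        totals = s[hhie_cols].apply(
            lambda col: col.map({"yes": 4, "sometimes": 2, "never": 0})
        ).sum(axis=1)
        failed = ~(
            ((s.heard_2k_left == 2) & (s.heard_500_left == 2))
            | ((s.heard_2k_right == 2) & (s.heard_500_right == 2))
        )
        present = [g for g in GRADE_ORDER if (t.grade == g).sum() >= 5]
        mean_hhie = [totals[t.grade == g].mean() for g in present]
        fail_rate = [failed[t.grade == g].mean() for g in present]
        assert mean_hhie == sorted(mean_hhie)
        assert fail_rate == sorted(fail_rate)


class TestOperatingCharacteristics:
    def test_bundle_fields_and_positive_discrimination(self, default_cohort_2000):
        bundle = protocol_operating_characteristics(default_cohort_2000)
        for key in ("n", "tp", "fp", "fn", "tn", "sensitivity", "specificity",
                    "ppv", "npv", "kappa", "auc", "optimal_cutoff", "youden_j",
                    "spearman"):
            assert key in bundle
        assert bundle["n"] == 2000
        # positive generative coefficients force positive discrimination
        assert bundle["auc"] > 0.5
        assert bundle["spearman"]["hhie"] > 0
        assert bundle["spearman"]["audiometry"] > 0

    def test_single_class_cohort_rejected(self):
        cohort = simulate_cohort(CohortParams(n=30, seed=3, target_prevalence=0.999))
        if cohort.truth.hearing_loss.nunique() == 1:
            with pytest.raises(ValueError):
                protocol_operating_characteristics(cohort)


class TestCorrelationHook:
    def test_gaussian_copula_induces_requested_association(self):
        k = 18
        corr = np.eye(k)
        corr[0, 1] = corr[1, 0] = 0.8  # male <-> overweight, arbitrary pair
        p = CohortParams(n=8000, seed=21, factor_correlation=corr.tolist())
        cohort = simulate_cohort(p)
        s = cohort.subjects
        male = (s.sex == "male").astype(int)
        over = (s.bmi >= 24).astype(int)
        # phi between binaries is attenuated relative to the latent 0.8:
        # with marginals 0.454 and 0.05 the attainable maximum is ~0.25
        assert np.corrcoef(male, over)[0, 1] > 0.15

    def test_independent_default_has_no_association(self):
        cohort = simulate_cohort(CohortParams(n=8000, seed=21))
        s = cohort.subjects
        male = (s.sex == "male").astype(int)
        over = (s.bmi >= 24).astype(int)
        assert abs(np.corrcoef(male, over)[0, 1]) < 0.05
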