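"""Validation statistics: confusion metrics, kappa, ROC, Spearman,
matrix reconstruction — each checked against an independent oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hearscreen.metrics import (
    ConfusionMatrix,
    cohen_kappa,
    confusion,
    matrix_metrics,
    reconstruct_matrix,
    roc_curve,
    round_half_up,
    spearman_rho,
    youden_threshold_to_operational,
)


def concordance_auc(scores, labels):
    """Pairwise-concordance oracle: P(score+ > score-) + 0.5 P(tie)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    pos, neg = s[y], s[~y]
    wins = (pos[:, None] > neg[None, :]).sum() + 0.5 * (pos[:, None] == neg[None, :]).sum()
    return wins / (len(pos) * len(neg))


class TestConfusion:
    @pytest.mark.parametrize("pred,truth,cells", [
        ([True, True], [True, False], (1, 1, 0, 0)),
        ([True, True, True], [True, True, True], (3, 0, 0, 0)),
        ([False, False, True], [True, False, True], (1, 0, 1, 1)),
    ])
    def test_cross_tabulation(self, pred, truth, cells):
        m = confusion(pred, truth)
        assert (m.tp, m.fp, m.fn, m.tn) == cells

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion([True], [True, False])


class TestMatrixMetrics:
    def test_verification_matrix_prints_published_percentages(self):
        mm = matrix_metrics(ConfusionMatrix(tp=51, fp=20, fn=0, tn=38))
        assert (mm.sensitivity_pct, mm.specificity_pct, mm.ppv_pct, mm.npv_pct) == (
            100.0, 65.5, 71.8, 100.0,
        )

    def test_perfect_matrix_all_100(self):
        mm = matrix_metrics(ConfusionMatrix(tp=1, fp=0, fn=0, tn=1))
        assert mm.sensitivity == mm.specificity == mm.ppv == mm.npv == 1.0

    def test_zero_fn_forces_npv_exactly_100(self):
        mm = matrix_metrics(ConfusionMatrix(tp=7, fp=13, fn=0, tn=5))
        assert mm.npv == 1.0 and mm.npv_pct == 100.0

    def test_zero_denominator_is_explicit_none(self):
        mm = matrix_metrics(ConfusionMatrix(tp=0, fp=0, fn=0, tn=4))
        assert mm.ppv is None and mm.sensitivity is None
        assert mm.npv_pct == 100.0

    @given(
        tp=st.integers(0, 40), fp=st.integers(0, 40),
        fn=st.integers(0, 40), tn=st.integers(0, 40),
    )
    @settings(derandomize=True, max_examples=1000)
    def test_textbook_formula_oracle(self, tp, fp, fn, tn):
        if tp + fp + fn + tn == 0:
            return
        m = ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn)
        mm = matrix_metrics(m)
        if tp + fn:
            assert mm.sensitivity == pytest.approx(tp / (tp + fn))
        if tn + fp:
            assert mm.specificity == pytest.approx(tn / (tn + fp))
        if tp + fp:
            assert mm.ppv == pytest.approx(tp / (tp + fp))
        if tn + fn:
            assert mm.npv == pytest.approx(tn / (tn + fn))
        assert mm.accuracy == pytest.approx((tp + tn) / m.total)


class TestKappa:
    def test_perfect_agreement_is_1(self):
        assert cohen_kappa(ConfusionMatrix(tp=5, fp=0, fn=0, tn=7)) == pytest.approx(1.0)

    def test_verification_matrix_rounds_to_published_value(self):
        k = cohen_kappa(ConfusionMatrix(tp=51, fp=20, fn=0, tn=38))
        assert k == pytest.approx(0.640, abs=5e-4)
        assert round_half_up(k, 1) == 0.6

    def test_degenerate_but_valid_marginal_gives_0(self):
        assert cohen_kappa(ConfusionMatrix(tp=3, fp=2, fn=0, tn=0)) == pytest.approx(0.0)

    def test_fully_degenerate_marginals_undefined(self):
        assert cohen_kappa(ConfusionMatrix(tp=5, fp=0, fn=0, tn=0)) is None

    @given(
        tp=st.integers(0, 30), fp=st.integers(0, 30),
        fn=st.integers(0, 30), tn=st.integers(0, 30),
    )
    @settings(derandomize=True, max_examples=1000, deadline=None)
    def test_bounds_symmetry_and_sklearn_oracle(self, tp, fp, fn, tn):
        n = tp + fp + fn + tn
        if n == 0:
            return
        m = ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn)
        k = cohen_kappa(m)
        # swapping both label conventions leaves kappa unchanged
        swapped = cohen_kappa(ConfusionMatrix(tp=tn, fp=fn, fn=fp, tn=tp))
        if k is None:
            assert swapped is None
            return
        assert -1.0 - 1e-12 <= k <= 1.0 + 1e-12
        assert swapped == pytest.approx(k)
        assert (k == pytest.approx(1.0)) == (fp == 0 and fn == 0 and tp > 0 and tn > 0)
        from sklearn.metrics import cohen_kappa_score

        pred = [True] * (tp + fp) + [False] * (fn + tn)
        truth = [True] * tp + [False] * fp + [True] * fn + [False] * tn
        expected = cohen_kappa_score(pred, truth)
        if not np.isnan(expected):
            assert k == pytest.approx(expected)


class TestROC:
    def test_perfect_separation(self):
        curve = roc_curve([4, 5, 6, 1, 2, 3], [1, 1, 1, 0, 0, 0])
        assert curve.auc == pytest.approx(1.0)
        assert curve.optimal_cutoff == pytest.approx(3.5)
        assert curve.optimal_j == pytest.approx(1.0)

    def test_single_shared_score_gives_chance_auc(self):
        assert roc_curve([2, 2, 2, 2], [1, 1, 0, 0]).auc == pytest.approx(0.5)

    def test_tied_scores_match_concordance_oracle(self):
        scores, labels = [3, 5, 2, 3], [True, True, False, False]
        curve = roc_curve(scores, labels)
        assert curve.auc == pytest.approx(0.875)
        assert curve.auc == pytest.approx(concordance_auc(scores, labels))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_curve([1, 2], [True, True])

    def test_cutoffs_strictly_increasing_and_bracket_scores(self):
        curve = roc_curve([1, 1, 4, 7], [0, 1, 0, 1])
        cuts = [p.cutoff for p in curve.points]
        assert cuts == sorted(cuts) and len(set(cuts)) == len(cuts)
        assert cuts[0] < 1 and cuts[-1] > 7

    def test_auc_matches_concordance_on_random_instances(self):
        rng = np.random.default_rng(42)
        checked = 0
        while checked < 150:
            n = int(rng.integers(4, 40))
            scores = rng.integers(0, 10, n)
            labels = rng.random(n) < rng.uniform(0.2, 0.8)
            if labels.all() or not labels.any():
                continue
            curve = roc_curve(scores.tolist(), labels.tolist())
            assert curve.auc == pytest.approx(concordance_auc(scores, labels))
            from sklearn.metrics import roc_auc_score

            assert curve.auc == pytest.approx(roc_auc_score(labels, scores))
            checked += 1

    def test_auc_invariant_under_strictly_increasing_transform(self):
        rng = np.random.default_rng(7)
        scores = rng.integers(0, 8, 60)
        labels = (rng.random(60) < 0.5).tolist()
        base = roc_curve(scores.tolist(), labels)
        squashed = roc_curve((scores ** 3 + 2 * scores).tolist(), labels)
        assert squashed.auc == pytest.approx(base.auc)
        assert [p.sensitivity for p in squashed.points] == pytest.approx(
            [p.sensitivity for p in base.points]
        )


class TestYoudenToOperational:
    @pytest.mark.parametrize("cutoff,expected", [(3.5, 4), (0.5, 1), (17.5, 18)])
    def test_ceiling_of_midpoint(self, cutoff, expected):
        assert youden_threshold_to_operational(cutoff) == expected

    @pytest.mark.parametrize("bad", [3.0, 3.25, 4])
    def test_non_midpoint_rejected(self, bad):
        with pytest.raises(ValueError):
            youden_threshold_to_operational(bad)


class TestSpearman:
    def test_monotone_and_reversed(self):
        x = [1.0, 2.0, 5.0, 9.0]
        assert spearman_rho(x, x) == pytest.approx(1.0)
        assert spearman_rho(x, x[::-1]) == pytest.approx(-1.0)

    def test_tied_example_equals_average_rank_pearson_oracle(self):
        x, y = [1, 2, 2, 3], [1, 3, 2, 4]
        rx, ry = np.array([1, 2.5, 2.5, 4]), np.array([1, 3, 2, 4])
        oracle = np.corrcoef(rx, ry)[0, 1]
        assert spearman_rho(x, y) == pytest.approx(oracle)

    def test_constant_vector_undefined(self):
        assert spearman_rho([1, 1, 1], [1, 2, 3]) is None

    def test_random_instances_match_rank_pearson(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            n = int(rng.integers(5, 30))
            x = rng.integers(0, 6, n).astype(float)
            y = x + rng.normal(0, 2, n)
            if np.all(x == x[0]):
                continue
            from scipy.stats import rankdata

            oracle = np.corrcoef(rankdata(x), rankdata(y))[0, 1]
            assert spearman_rho(x, y) == pytest.approx(oracle)


class TestReconstruct:
    def test_published_verification_metrics_pin_down_a_unique_matrix(self):
        sols = reconstruct_matrix(109, sensitivity_pct=100.0,
                                  specificity_pct=65.5, ppv_pct=71.8)
        assert sols == [ConfusionMatrix(tp=51, fp=20, fn=0, tn=38)]

    def test_trivial_two_subject_case(self):
        sols = reconstruct_matrix(2, sensitivity_pct=100.0,
                                  specificity_pct=100.0, ppv_pct=100.0)
        assert ConfusionMatrix(tp=1, fp=0, fn=0, tn=1) in sols
        assert all(m.fp == 0 and m.fn == 0 for m in sols)

    def test_contradictory_constraints_give_empty_set(self):
        assert reconstruct_matrix(10, sensitivity_pct=0.0,
                                  specificity_pct=100.0, ppv_pct=50.0) == []

    def test_solutions_round_trip_through_matrix_metrics(self):
        sols = reconstruct_matrix(40, sensitivity_pct=75.0, specificity_pct=50.0)
        assert sols
        for m in sols:
            mm = matrix_metrics(m)
            assert mm.sensitivity_pct == 75.0
            assert mm.specificity_pct == 50.0


def test_round_half_up_ties_go_up():
    assert round_half_up(0.25, 1) == 0.3
    assert round_half_up(65.45, 1) == 65.5
    assert round_half_up(2.5, 0) == 3.0
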