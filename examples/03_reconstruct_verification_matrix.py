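"""Recover an integer confusion matrix from rounded published metrics.

Given a verification cohort of n=109 with published sensitivity 100%,
specificity 65.5% and PPV 71.8%, exhaustive search over all integer 2x2
matrices shows exactly one is consistent — from which NPV and Cohen's
kappa follow without access to the raw data.
"""

from hearscreen import cohen_kappa, matrix_metrics, reconstruct_matrix
from hearscreen.metrics import round_half_up

solutions = reconstruct_matrix(
    109, sensitivity_pct=100.0, specificity_pct=65.5, ppv_pct=71.8
)
print(f"consistent matrices: {len(solutions)}")
m = solutions[0]
print(f"unique solution: TP={m.tp} FP={m.fp} FN={m.fn} TN={m.tn}")

mm = matrix_metrics(m)
kappa = cohen_kappa(m)
print(f"sensitivity {mm.sensitivity_pct}%  specificity {mm.specificity_pct}%")
print(f"PPV {mm.ppv_pct}%  NPV {mm.npv_pct}%")
print(f"kappa {kappa:.4f} (rounds to {round_half_up(kappa, 1)})")
# Zero false negatives force both sensitivity and NPV to exactly 100%;
# the kappa of 0.64 indicates substantial screen/reference agreement.
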