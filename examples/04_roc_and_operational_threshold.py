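"""ROC analysis of the cumulative risk score and the operational cutoff.

Computes the ROC curve of the 18-factor score against the reference
standard on a simulated cohort.  Candidate cutoffs are midpoints between
consecutive integer scores; the Youden-optimal midpoint (e.g. 3.5) maps to
the smallest integer score called positive (e.g. 4).
"""

from hearscreen import (
    CohortParams,
    cumulative_score,
    derive_risk_factors,
    records_from_frame,
    roc_curve,
    simulate_cohort,
    youden_threshold_to_operational,
)

cohort = simulate_cohort(CohortParams(n=1500, seed=8))
records = records_from_frame(cohort.subjects)
scores = [cumulative_score(derive_risk_factors(r.profile)) for r in records]
truth = cohort.truth.hearing_loss.astype(bool).tolist()

curve = roc_curve(scores, truth)
print(f"AUC = {curve.auc:.3f}")
print(f"Youden-optimal cutoff = {curve.optimal_cutoff} (J = {curve.optimal_j:.3f})")
print(f"operational threshold: score >= "
      f"{youden_threshold_to_operational(curve.optimal_cutoff)} is high risk")
print("\ncutoff  sens   spec   J")
for p in curve.points:
    print(f"{p.cutoff:6.1f}  {p.sensitivity:5.3f}  {p.specificity:5.3f}  {p.youden_j:+.3f}")
# AUC measures how well the raw factor count ranks subjects with loss above
# those without; J = sensitivity + specificity - 1 picks the operating point.
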