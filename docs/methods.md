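# Methods

## The screening protocol

The screen layers three instruments that trade accuracy for cost in
different ways, then combines them disjunctively.

**Risk score.** Each of 18 binary indicators contributes one point;
no weighting is applied (the score is a count, which is what makes it
administrable as a checklist). Operational definitions that involve
arithmetic are resolved before the score: overweight/obesity is
BMI ≥ 24.0 kg/m² (boundary inclusive; the Asian-population cutoff), with
BMI derived as weight/(height in m)² when not supplied; widowed/divorced is
any non-married status; "no exercise" is the negation of a regular exercise
habit. Behavioural exposures (smoking, drinking, occupational noise,
headset use) reach the library as pre-resolved booleans because the
questionnaire front-end applies their duration criteria. Age is *not* a
factor: in a population restricted to 60+, age is better treated as a
background variable (it does enter the simulator's generative model).
A chronic otitis media history is carried on the profile but is not scored.

The score is dichotomised at a configurable threshold, default 4, the
ceiling of the Youden-optimal ROC midpoint 3.5. `roc_curve` evaluates
cutoffs at midpoints between consecutive observed scores plus sentinels
beyond the extremes, calls a subject positive when score > cutoff, computes
AUC by the trapezoidal rule over (1 − specificity, sensitivity) — points
sorted by (FPR, TPR) so vertical runs are traversed upward; this makes the
trapezoidal area identical to the pairwise-concordance (Mann–Whitney)
statistic, which the tests verify — and breaks Youden ties toward the
smallest cutoff, i.e. the most sensitive operating point, appropriate for a
screen whose purpose is not to miss cases.

**HHIE-s.** Totals are even by construction (items score 4/2/0), so an odd
total is treated as corrupted input, not rounded into a band. The bands
0–8 / 10–22 / 24–40 and the abnormality rule total ≥ 10 are fixed;
emotional/situational subscales (items 1–5 / 6–10) are exposed but unused
by any decision.

**Two-step tone test.** The per-ear decision tree is short-circuiting: the
0.5 kHz count is never consulted (and must not be present) when the 2 kHz
step failed, mirroring how the tones are actually administered. The
binaural combination is pass-if-either-ear-passes. This is a design
decision, not protocol text: since the reference standard is the
*better-ear* PTA average, a screen that fails only when both ears fail
targets the same quantity; it is also the only combination consistent with
the validated 100% sensitivity / 100% NPV of the overall conclusion.

**Triage.** Screen-positive ⇔ any component positive (OR rule); positive
subjects re-screen at 3 months, negative at 6; GP referral mirrors the
tone-test failure specifically, because only that component indicates
probable moderate-or-worse loss rather than elevated risk. The OR rule for
mixed component patterns is likewise a documented design decision — the
protocol only fixes the all-negative and all-positive corners — chosen to
maximise sensitivity.

**PTA reference.** Grades partition the dB axis with inclusive upper
edges: normal ≤ 25 < mild ≤ 40 < moderate ≤ 55 < moderately severe ≤ 70
< severe ≤ 90 < profound. Literature band labels quote integer ranges
(26–40 etc.); extending each lower band upward closes the non-integer gaps
while preserving the two binary decisions (> 25, > 40) exactly, so
non-integer averages need no rounding convention.

## Validation statistics

Sensitivity, specificity, PPV, NPV and accuracy are simple ratios; a zero
denominator yields an explicit `None`, never NaN. Cohen's κ uses
p₀ = (TP+TN)/n and pₑ from the marginals. Display values round half-up to
one decimal in percent (κ to one decimal), the reporting precision of the
screening literature; full-precision fractions are always available.
Spearman ρ delegates to `scipy.stats.spearmanr` (average ranks for ties)
behind the package's own validation and undefined-case handling; the test
suite cross-checks it against an independently coded rank-Pearson oracle,
and κ/AUC against scikit-learn.

`reconstruct_matrix` enumerates every non-negative integer (TP, FP, FN, TN)
with the given total and keeps those whose requested metrics round
(half-up, one decimal) to the published values. For n = 109 with
sensitivity 100.0%, specificity 65.5% and PPV 71.8% the solution is unique
(TP=51, FP=20, FN=0, TN=38), which is what licenses quoting its κ = 0.64
and NPV = 100.0% without raw data. An empty result means the constraints
are contradictory; multiple results mean the published rounding does not
pin the table down — both are returned as data, not errors.

## The synthetic cohort generator

`simulate_cohort` emulates the cross-sectional structure the screen
assumes, with one integer seed fixing the entire stream.

* **Age**: normal(71.0, 6.1) years truncated below at 60, floored to
  integers — the reference community cohort's moments.
* **Factors**: independent Bernoulli draws at the configured prevalences
  (community values where published, e.g. hypertension 0.643, diabetes
  0.307, no-exercise 0.481, headset use 0.072; factors with no published
  prevalence default to 0.05). A Gaussian-copula hook accepts an 18×18
  correlation matrix for sensitivity analyses; the default is
  independence because no covariance structure is published. Consequence:
  the simulated risk-score AUC (~0.63–0.66) is *expected* to fall short of
  AUCs reported on real cohorts (~0.78), which arise from correlated
  factors and the age gradient the score deliberately omits.
* **Hearing loss**: Bernoulli with p = expit(α + β_age·(age − 71) + Σβ·x),
  β from the published multivariate community fit (diabetes 1.461,
  hypothyroidism 1.645, noise 1.357, hyperuricemia 1.155, non-light diet
  0.894, drinking 0.741, hypertension 0.609, cardio/cerebrovascular 0.362,
  hyperlipidemia 0.246, widowed/divorced 0.148, male −0.056, overweight
  −0.081, no-exercise −0.385, age 0.104/yr). Factors absent from that fit,
  or whose univariate estimates were degenerate (headset use, ototoxic
  drugs, near-zero positive counts), get β = 0. The intercept α is not
  published; `calibrate_intercept` finds it by bisection on a 200,000-draw
  quasi-population (seeded deterministically from the cohort seed) so the
  population-mean probability hits the target prevalence, default 0.798,
  to within 10⁻⁴. With all β = 0 it reduces to logit(target) in closed
  form.
* **Grades**: normal when no loss; otherwise mild/moderate/moderately
  severe/severe/profound in proportions 48.5 : 23.4 : 7.8 : 1.3 : 0.7,
  renormalised within the loss class (the published constituent ratios sum
  to 81.7% against a 79.8% prevalence; renormalisation treats the
  prevalence as authoritative and the ratios as a conditional mix).
* **Thresholds**: the better-ear 4-frequency average is uniform within the
  grade's dB band (normal capped below 25, profound at 110), drawn 0.25 dB
  off the band edges so the grade recomputed from the 0.1-dB-rounded
  per-frequency thresholds can never cross a boundary. Per-frequency
  thresholds add a zero-mean tilt rising with frequency (uniform 2–8
  dB/step slope plus N(0,2) noise, re-centred; damped near the plausible
  range ends) — the sloping configuration of presbycusis — so the
  4-frequency mean is preserved exactly. The worse ear adds an
  exponential(10 dB) offset; which side is better is a fair coin.
* **HHIE-s link**: per item, an ordinal-logistic draw with severity
  s = (better-ear avg − 25)/10 dB and cutpoints (1.8, 4.0):
  P(yes) = expit(s − 4.0), P(yes or sometimes) = expit(s − 1.8). The
  cutpoints and slope were chosen once so that a 40 dB average — the
  moderate-loss boundary — yields an expected item mean of ≈1 point and
  hence ≈50% abnormal totals; this is a documented convention, not
  protocol text.
* **Tone trials**: each presentation is heard with probability
  expit((level − threshold at that frequency)/3 dB), independently;
  `tone_slope=0` gives the noiseless step function. The 0.5 kHz counts are
  generated only for ears that heard the 2 kHz tone twice, so simulated
  rows satisfy the sequential-administration invariant by construction.

**What the generator does not emulate:** factor–factor and factor–age
correlation (by default), measurement error in PTA itself, informative
non-response, test–retest learning effects, and ambient-noise or device
variation in the tone test. Tests passing on simulated cohorts therefore
demonstrate the *internal* consistency and calibration of the pipeline —
not field performance, which depends on exactly the dependencies the
default simulator omits.

## Numerical and interface choices

* Missing profile fields are hard errors naming the row and column; the
  opt-in `assume_absent` mode imputes False with a logged warning.
  Conservative screening defaults must be explicit, never silent.
* Booleans serialise as 0/1, decimals with '.', blank meaning
  "not administered" for the conditional 0.5 kHz counts; outputs are
  written atomically (temp file + rename), so failed runs leave nothing
  behind, and identical inputs give byte-identical outputs.
* `reconstruct_matrix` is O(n³) in the worst case but constraint
  short-circuiting makes n ≈ 100 instantaneous (< 0.1 s).
* Problem sizes in the test and acceptance suites — prevalence calibration
  at n = 100,000, coefficient recovery at n = 5,000 over five seeds,
  operating characteristics at n = 2,000 — were chosen so Monte-Carlo
  standard errors are small relative to the tolerances being checked while
  the whole suite stays interactive (≈10 s).

## Known limitations

* The operational threshold 4 is a configuration value, not re-derived:
  re-deriving it would require the original cohort, and on simulated data
  the optimum reflects the simulator, not the field instrument.
* Published report-level inconsistencies are resolved by documented
  choices: the male prevalence 45.4% (182/401) over a conflicting printed
  38.4%; the maximum Youden index as reported, not reconciled with the
  separately printed sensitivity/specificity pair; the grade mix
  renormalised as above.
* Confidence intervals are not produced; `roc_curve` reports point
  estimates only.
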