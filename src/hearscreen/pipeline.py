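"""Orchestration: run the three-component screen over parsed subject
records and compute operating characteristics against the PTA reference.

Kept free of file I/O so the same code path serves the CLI, the simulator's
self-validation and the tests.
"""

from __future__ import annotations

from typing import TYPE_CHECKING, Optional, Sequence

from . import audiometry, hhie, metrics, risk, triage

if TYPE_CHECKING:  # pragma: no cover
    from .io import SubjectRecord

__all__ = ["ScreenRow", "screen_records", "operating_characteristics"]


class ScreenRow(dict):
    """One conclusions.csv row; a plain dict with fixed keys."""

    KEYS = (
        "subject_id",
        "risk_score",
        "risk_stratum",
        "hhie_total",
        "hhie_category",
        "audiometry_overall",
        "screen_positive",
        "rescreen_interval_months",
        "refer_to_gp",
    )


def screen_records(
    records: Sequence["SubjectRecord"], threshold: int = risk.DEFAULT_THRESHOLD
) -> list[ScreenRow]:
    """Apply risk scoring, HHIE-s and the two-step audiometry per subject."""
    rows: list[ScreenRow] = []
    for rec in records:
        sid = rec.profile.subject_id
        if rec.hhie is None:
            raise ValueError(f"subject {sid}: HHIE-s responses missing")
        if rec.left_trial is None or rec.right_trial is None:
            raise ValueError(f"subject {sid}: audiometry trials missing")
        assessment = risk.assess(rec.profile, threshold=threshold)
        hres = hhie.evaluate_hhie(rec.hhie)
        ares = audiometry.two_step_binaural(rec.left_trial, rec.right_trial)
        conclusion = triage.conclude(
            assessment.stratum,
            hres.abnormal,
            ares.overall is audiometry.EarResult.failed,
        )
        rows.append(
            ScreenRow(
                subject_id=sid,
                risk_score=assessment.score,
                risk_stratum=assessment.stratum.value,
                hhie_total=hres.total,
                hhie_category=hres.category.value,
                audiometry_overall=ares.overall.value,
                screen_positive=int(conclusion.screen_positive),
                rescreen_interval_months=conclusion.rescreen_interval_months,
                refer_to_gp=int(conclusion.refer_to_gp),
            )
        )
    return rows


def operating_characteristics(
    rows: Sequence[ScreenRow],
    truth: Sequence[bool],
    pta_better_avg: Optional[Sequence[float]] = None,
) -> dict:
    """Validation bundle of screen calls against the reference standard.

    ``truth`` is the binary hearing-loss reference (better-ear average
    > 25 dB HL); ``pta_better_avg`` enables the Spearman correlations of
    each component with the continuous reference.
    """
    if len(rows) != len(truth):
        raise ValueError("rows and truth lengths differ")
    pred = [bool(r["screen_positive"]) for r in rows]
    cm = metrics.confusion(pred, list(truth))
    mm = metrics.matrix_metrics(cm)
    kappa = metrics.cohen_kappa(cm)
    scores = [r["risk_score"] for r in rows]
    roc = metrics.roc_curve(scores, list(truth))

    spearman: dict[str, Optional[float]] = {}
    if pta_better_avg is not None:
        if len(pta_better_avg) != len(rows):
            raise ValueError("pta_better_avg length differs from rows")
        pta = list(pta_better_avg)
        spearman = {
            "hhie": metrics.spearman_rho(pta, [r["hhie_total"] for r in rows]),
            "risk_score": metrics.spearman_rho(pta, scores),
            "audiometry": metrics.spearman_rho(
                pta, [float(r["audiometry_overall"] == "failed") for r in rows]
            ),
        }

    bundle = {
        "n": cm.total,
        "tp": cm.tp,
        "fp": cm.fp,
        "fn": cm.fn,
        "tn": cm.tn,
        "sensitivity": mm.sensitivity,
        "specificity": mm.specificity,
        "ppv": mm.ppv,
        "npv": mm.npv,
        "accuracy": mm.accuracy,
        "kappa": kappa,
        "auc": roc.auc,
        "optimal_cutoff": roc.optimal_cutoff,
        "youden_j": roc.optimal_j,
        "spearman": spearman,
        "display": {
            "sensitivity": mm.sensitivity_pct,
            "specificity": mm.specificity_pct,
            "ppv": mm.ppv_pct,
            "npv": mm.npv_pct,
            "accuracy": mm.accuracy_pct,
            "kappa": None if kappa is None else metrics.round_half_up(kappa, 1),
        },
    }
    return bundle
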