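"""CSV / JSON / YAML interchange for the screening pipeline.

subjects.csv carries one row per subject: profile fields (booleans as
0/1), HHIE-s items ``hhie_q1..hhie_q10`` (yes/sometimes/never,
case-insensitive on read), tone-trial counts ``heard_2k_left`` etc.
(blank = tone not administered) and, optionally, the reference pure-tone
thresholds ``pta_left_500 .. pta_right_4000``.  conclusions.csv and
metrics.json are the pipeline outputs.  Outputs are written atomically:
a failed run never leaves a partial file behind.
"""

from __future__ import annotations

import json
import logging
import math
import os
import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict

from . import risk
from .audiometry import EarTrial, PTARecord, pta_classify
from .hhie import HHIEResponses
from .pipeline import ScreenRow, operating_characteristics, screen_records
from .risk import SubjectProfile

logger = logging.getLogger("hearscreen")

__all__ = [
    "SubjectRecord",
    "RunConfig",
    "PROFILE_BOOL_COLUMNS",
    "read_subjects",
    "records_from_frame",
    "record_from_row",
    "write_conclusions",
    "write_metrics_json",
    "run_screen",
]

PROFILE_BOOL_COLUMNS = (
    "lives_alone",
    "noise_history",
    "family_deafness",
    "exercise_habit",
    "smoking",
    "drinking",
    "headset_habit",
    "hypertension",
    "diabetes",
    "hyperlipidemia",
    "cardio_cerebrovascular",
    "hyperuricemia",
    "hypothyroidism",
    "ototoxic_drug_history",
    "chronic_otitis_media",
)

_PROFILE_COLUMNS = (
    ("subject_id", "age", "sex", "height", "weight", "bmi", "marital_status", "diet")
    + PROFILE_BOOL_COLUMNS
)
_HHIE_COLUMNS = tuple(f"hhie_q{i}" for i in range(1, 11))
_TRIAL_COLUMNS = ("heard_2k_left", "heard_500_left", "heard_2k_right", "heard_500_right")
_PTA_COLUMNS = tuple(
    f"pta_{side}_{f}" for side in ("left", "right") for f in (500, 1000, 2000, 4000)
)
_KNOWN_COLUMNS = set(_PROFILE_COLUMNS) | set(_HHIE_COLUMNS) | set(_TRIAL_COLUMNS) | set(
    _PTA_COLUMNS
)


@dataclass(frozen=True)
class SubjectRecord:
    """A parsed subjects.csv row: profile plus whichever sections are present."""

    profile: SubjectProfile
    hhie: Optional[HHIEResponses]
    left_trial: Optional[EarTrial]
    right_trial: Optional[EarTrial]
    pta: Optional[PTARecord]
    row_number: Optional[int] = None


class RunConfig(BaseModel):
    """Configuration of one `screen` run."""

    model_config = ConfigDict(frozen=True)

    input: Path
    conclusions_out: Path
    metrics_out: Optional[Path] = None
    threshold: int = risk.DEFAULT_THRESHOLD
    assume_absent: bool = False
    validate_against_pta: bool = False


def _is_missing(value) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and math.isnan(value):
        return True
    return isinstance(value, str) and value.strip() == ""


def _parse_bool(value, column: str) -> bool:
    if isinstance(value, (bool,)):
        return value
    if isinstance(value, (int, float)) and not isinstance(value, bool):
        if float(value) in (0.0, 1.0):
            return bool(value)
        raise ValueError(f"column {column!r}: boolean must be 0 or 1, got {value!r}")
    s = str(value).strip().lower()
    if s in ("1", "true", "yes"):
        return True
    if s in ("0", "false", "no"):
        return False
    raise ValueError(f"column {column!r}: boolean must be 0 or 1, got {value!r}")


def _get(row, column: str):
    try:
        return row[column]
    except KeyError:
        return None


def record_from_row(
    row, row_number: Optional[int] = None, assume_absent: bool = False
) -> SubjectRecord:
    """Build a validated :class:`SubjectRecord` from one mapping/Series row.

    With ``assume_absent`` missing profile booleans are treated as False
    (each substitution is logged); by default a missing field is an error —
    silent imputation is never the default for a screening decision.
    """
    where = f"row {row_number}" if row_number is not None else "row"
    kwargs: dict = {}
    for col in ("subject_id", "sex", "marital_status", "diet"):
        v = _get(row, col)
        if _is_missing(v):
            raise ValueError(f"{where}: required column {col!r} missing or empty")
        kwargs[col] = str(v).strip().lower() if col != "subject_id" else str(v)
    age = _get(row, "age")
    if _is_missing(age):
        raise ValueError(f"{where}: required column 'age' missing or empty")
    kwargs["age"] = int(float(age))
    for col in ("height", "weight", "bmi"):
        v = _get(row, col)
        kwargs[col] = None if _is_missing(v) else float(v)
    for col in PROFILE_BOOL_COLUMNS:
        v = _get(row, col)
        if _is_missing(v):
            if col == "chronic_otitis_media":
                kwargs[col] = False
                continue
            if assume_absent:
                logger.warning("%s: missing %s treated as absent (0)", where, col)
                kwargs[col] = False
                continue
            raise ValueError(f"{where}: required column {col!r} missing or empty")
        else:
            kwargs[col] = _parse_bool(v, col)

    try:
        profile = SubjectProfile(**kwargs)
    except Exception as exc:
        raise ValueError(f"{where}: {exc}") from exc

    hhie_resp = None
    hhie_values = [_get(row, c) for c in _HHIE_COLUMNS]
    if not all(_is_missing(v) for v in hhie_values):
        items = []
        for col, v in zip(_HHIE_COLUMNS, hhie_values):
            if _is_missing(v):
                raise ValueError(f"{where}: HHIE item {col!r} missing")
            items.append(str(v).strip().lower())
        try:
            hhie_resp = HHIEResponses(items=tuple(items))
        except Exception as exc:
            raise ValueError(f"{where}: {exc}") from exc

    def trial(side: str) -> Optional[EarTrial]:
        h2k = _get(row, f"heard_2k_{side}")
        h500 = _get(row, f"heard_500_{side}")
        if _is_missing(h2k):
            if not _is_missing(h500):
                raise ValueError(
                    f"{where}: heard_500_{side} present without heard_2k_{side}"
                )
            return None
        try:
            return EarTrial(
                heard_2k=int(float(h2k)),
                heard_500=None if _is_missing(h500) else int(float(h500)),
            )
        except Exception as exc:
            raise ValueError(f"{where}: {side} ear trial: {exc}") from exc

    left_trial = trial("left")
    right_trial = trial("right")

    pta = None
    pta_values = [_get(row, c) for c in _PTA_COLUMNS]
    if not all(_is_missing(v) for v in pta_values):
        missing = [c for c, v in zip(_PTA_COLUMNS, pta_values) if _is_missing(v)]
        if missing:
            raise ValueError(f"{where}: incomplete PTA reference, missing {missing}")
        vals = [float(v) for v in pta_values]
        try:
            pta = pta_classify(vals[:4], vals[4:])
        except Exception as exc:
            raise ValueError(f"{where}: {exc}") from exc

    return SubjectRecord(
        profile=profile,
        hhie=hhie_resp,
        left_trial=left_trial,
        right_trial=right_trial,
        pta=pta,
        row_number=row_number,
    )


def records_from_frame(
    frame: pd.DataFrame, assume_absent: bool = False
) -> list[SubjectRecord]:
    """Parse and validate every row of an in-memory subjects frame."""
    unknown = [c for c in frame.columns if c not in _KNOWN_COLUMNS]
    if unknown:
        logger.warning("ignoring unknown columns: %s", unknown)
    records = []
    seen: set[str] = set()
    for i, (_, row) in enumerate(frame.iterrows()):
        rec = record_from_row(row, row_number=i + 1, assume_absent=assume_absent)
        sid = rec.profile.subject_id
        if sid in seen:
            raise ValueError(f"duplicate subject_id {sid!r} at row {i + 1}")
        seen.add(sid)
        records.append(rec)
    return records


def read_subjects(path: str | Path, assume_absent: bool = False) -> list[SubjectRecord]:
    """Read and validate subjects.csv; errors name the offending row/column."""
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    if frame.empty:
        raise ValueError(f"{path}: no subject rows")
    return records_from_frame(frame, assume_absent=assume_absent)


def _atomic_write_text(path: Path, text: str) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.", suffix=".tmp")
    try:
        with os.fdopen(fd, "w", encoding="utf-8", newline="") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_conclusions(rows: Sequence[ScreenRow], path: str | Path) -> None:
    frame = pd.DataFrame(list(rows), columns=list(ScreenRow.KEYS))
    _atomic_write_text(Path(path), frame.to_csv(index=False))


def write_metrics_json(bundle: dict, path: str | Path) -> None:
    _atomic_write_text(Path(path), json.dumps(bundle, indent=2, sort_keys=True) + "\n")


def write_subjects(frame: pd.DataFrame, path: str | Path) -> None:
    """Write a subjects/truth frame with the canonical serialisation
    (booleans 0/1, '.' decimal separator, blank for not-administered)."""
    _atomic_write_text(Path(path), frame.to_csv(index=False))


def write_params_yaml(params_dict: dict, path: str | Path) -> None:
    _atomic_write_text(
        Path(path), yaml.safe_dump(params_dict, sort_keys=True, default_flow_style=False)
    )


def run_screen(config: RunConfig) -> dict:
    """Screen a subjects file; optionally validate against its PTA columns.

    Returns the metrics bundle (empty dict when validation is off).  All
    outputs are written atomically after the whole computation succeeds.
    """
    records = read_subjects(config.input, assume_absent=config.assume_absent)
    rows = screen_records(records, threshold=config.threshold)

    bundle: dict = {}
    if config.validate_against_pta:
        missing = [r.profile.subject_id for r in records if r.pta is None]
        if missing:
            raise ValueError(
                f"validation requested but PTA reference missing for subjects {missing[:5]}"
                + ("..." if len(missing) > 5 else "")
            )
        truth = [r.pta.hearing_loss for r in records]  # type: ignore[union-attr]
        pta_avg = [r.pta.better_ear_avg for r in records]  # type: ignore[union-attr]
        bundle = operating_characteristics(rows, truth, pta_avg)

    write_conclusions(rows, config.conclusions_out)
    if config.validate_against_pta and config.metrics_out is not None:
        write_metrics_json(bundle, config.metrics_out)
    return bundle
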