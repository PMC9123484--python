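"""Exam and cohort I/O, reliability factors, and the reliability exclusion rule.

Exam CSV dialect
----------------
Long format, UTF-8, "." decimal separator.  One ``meta`` row per exam carries
the catch-trial counts, followed by one ``point`` row per stimulus location::

    subject_id,eye,test_index,day_index,row_type,point_id,sensitivity_db,false_positives,false_negatives,catch_trials
    s01,OD,1,1,meta,,,1,2,20
    s01,OD,1,1,point,0,12.5,,,
    ...

Missing cohort values (an eye with no reliable test) are encoded as empty
cells, never 0: a sensitivity of 0 dB is a legal measurement (the floor).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .grid import Eye, N_POINTS

__all__ = [
    "ExamRecord",
    "CohortRow",
    "ReliabilityUndefinedError",
    "ExamFormatError",
    "compute_rf",
    "filter_reliable",
    "read_exams",
    "write_exams",
    "read_cohort_table",
    "write_cohort_table",
    "cohort_to_frame",
    "RF_THRESHOLD",
]

#: Reliability-factor exclusion threshold: exams with RF strictly greater than
#: 25% are excluded (ties kept).
RF_THRESHOLD = 0.25


class ReliabilityUndefinedError(ValueError):
    """Raised when the reliability factor is undefined (no catch trials)."""


class ExamFormatError(ValueError):
    """Raised on malformed exam or cohort files."""


def compute_rf(false_positives: int, false_negatives: int, catch_trials: int) -> float:
    """Reliability factor: (false positives + false negatives) / catch trials.

    Raises :class:`ReliabilityUndefinedError` if no catch trials were
    presented, and ``ValueError`` if the error counts exceed the catch trials.
    """
    if catch_trials <= 0:
        raise ReliabilityUndefinedError(
            "reliability factor undefined: no catch trials presented"
        )
    if false_positives < 0 or false_negatives < 0:
        raise ValueError("catch-trial counts must be non-negative")
    if false_positives + false_negatives > catch_trials:
        raise ValueError("false responses exceed the number of catch trials")
    return (false_positives + false_negatives) / catch_trials


@dataclass(frozen=True)
class ExamRecord:
    """One eye's one perimetry test: pointwise dB sensitivities + reliability."""

    subject_id: str
    eye: Eye
    test_index: int
    day_index: int
    sensitivities: np.ndarray
    false_positives: int
    false_negatives: int
    catch_trials: int

    def __post_init__(self) -> None:
        s = np.asarray(self.sensitivities, dtype=float)
        object.__setattr__(self, "sensitivities", s)
        object.__setattr__(self, "eye", Eye(self.eye))
        if s.ndim != 1 or len(s) != N_POINTS:
            raise ValueError(
                f"exam {self.subject_id}/{self.eye}/{self.test_index}: expected "
                f"{N_POINTS} sensitivities, got {len(s)}"
            )
        if np.any(~np.isfinite(s)) or np.any(s < 0):
            raise ValueError(
                f"exam {self.subject_id}/{self.eye}/{self.test_index}: "
                "sensitivities must be finite and >= 0 dB"
            )
        # validates counts
        compute_rf(self.false_positives, self.false_negatives, self.catch_trials)

    @property
    def reliability_factor(self) -> float:
        return compute_rf(self.false_positives, self.false_negatives, self.catch_trials)

    @property
    def key(self) -> tuple[str, str, int]:
        return (self.subject_id, self.eye.value, self.test_index)


@dataclass(frozen=True)
class CohortRow:
    """Per subject/eye summary row (Table-1-style cohort table)."""

    subject_id: str
    eye: Eye
    best_vision_sphere: float
    bcva: float
    oms: float | None = None
    v_tot: float | None = None
    age: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "eye", Eye(self.eye))


def filter_reliable(
    exams: Sequence[ExamRecord], threshold: float = RF_THRESHOLD
) -> tuple[list[ExamRecord], list[ExamRecord]]:
    """Split exams into (kept, excluded) by the reliability rule.

    An exam is excluded iff its reliability factor is *strictly greater* than
    ``threshold`` (the boundary value is kept).  Input order is preserved.
    """
    if len(exams) == 0:
        raise ValueError("no exams supplied")
    kept = [e for e in exams if e.reliability_factor <= threshold]
    excluded = [e for e in exams if e.reliability_factor > threshold]
    return kept, excluded


# --- exam CSV ----------------------------------------------------------------

_EXAM_COLUMNS = [
    "subject_id", "eye", "test_index", "day_index", "row_type", "point_id",
    "sensitivity_db", "false_positives", "false_negatives", "catch_trials",
]


def write_exams(exams: Iterable[ExamRecord], path: str | Path) -> None:
    """Write exams in the package's long CSV dialect (lossless round trip)."""
    rows = []
    for e in exams:
        rows.append(
            {
                "subject_id": e.subject_id, "eye": e.eye.value,
                "test_index": e.test_index, "day_index": e.day_index,
                "row_type": "meta", "point_id": "", "sensitivity_db": "",
                "false_positives": e.false_positives,
                "false_negatives": e.false_negatives,
                "catch_trials": e.catch_trials,
            }
        )
        for pid, s in enumerate(e.sensitivities):
            rows.append(
                {
                    "subject_id": e.subject_id, "eye": e.eye.value,
                    "test_index": e.test_index, "day_index": e.day_index,
                    "row_type": "point", "point_id": pid,
                    "sensitivity_db": np.format_float_positional(s, trim="0"),
                    "false_positives": "", "false_negatives": "", "catch_trials": "",
                }
            )
    pd.DataFrame(rows, columns=_EXAM_COLUMNS).to_csv(path, index=False)


def read_exams(path: str | Path) -> list[ExamRecord]:
    """Read exams from the package CSV dialect, validating per-exam structure."""
    try:
        df = pd.read_csv(path, dtype={"subject_id": str})
    except pd.errors.EmptyDataError as exc:
        raise ExamFormatError(f"{path}: empty exam file") from exc
    missing = set(_EXAM_COLUMNS) - set(df.columns)
    if missing:
        raise ExamFormatError(f"{path}: missing columns {sorted(missing)}")
    exams: list[ExamRecord] = []
    for (subj, eye, test, day), g in df.groupby(
        ["subject_id", "eye", "test_index", "day_index"], sort=False
    ):
        meta = g[g["row_type"] == "meta"]
        pts = g[g["row_type"] == "point"]
        where = f"{path}: exam {subj}/{eye}/test {test}"
        if len(meta) != 1:
            raise ExamFormatError(f"{where}: expected exactly one meta row, got {len(meta)}")
        if len(pts) != N_POINTS:
            raise ExamFormatError(f"{where}: expected {N_POINTS} point rows, got {len(pts)}")
        pids = pd.to_numeric(pts["point_id"], errors="coerce")
        if pids.isna().any() or sorted(pids.astype(int)) != list(range(N_POINTS)):
            raise ExamFormatError(f"{where}: point_id must cover 0..{N_POINTS - 1} exactly once")
        sens = pd.to_numeric(pts["sensitivity_db"], errors="coerce").to_numpy()
        if np.any(~np.isfinite(sens)):
            bad = pts.index[~np.isfinite(sens)][0] + 2  # header + 1-based
            raise ExamFormatError(f"{where}: non-numeric sensitivity near file row {bad}")
        if np.any(sens < 0):
            bad = pts.index[sens < 0][0] + 2
            raise ExamFormatError(f"{where}: negative sensitivity at file row {bad}")
        order = np.argsort(pids.to_numpy())
        m = meta.iloc[0]
        try:
            exams.append(
                ExamRecord(
                    subject_id=str(subj), eye=Eye(str(eye)),
                    test_index=int(test), day_index=int(day),
                    sensitivities=sens[order],
                    false_positives=int(m["false_positives"]),
                    false_negatives=int(m["false_negatives"]),
                    catch_trials=int(m["catch_trials"]),
                )
            )
        except (ValueError, TypeError) as exc:
            raise ExamFormatError(f"{where}: {exc}") from exc
    if not exams:
        raise ExamFormatError(f"{path}: no exams found")
    return exams


# --- cohort CSV --------------------------------------------------------------

_COHORT_COLUMNS = ["subject_id", "eye", "best_vision_sphere_d", "bcva_logmar",
                   "oms_db", "v_tot_dbsr"]


def write_cohort_table(rows: Iterable[CohortRow], path: str | Path) -> None:
    df = cohort_to_frame(rows)
    df.to_csv(path, index=False)


def cohort_to_frame(rows: Iterable[CohortRow]) -> pd.DataFrame:
    """Cohort rows as a DataFrame (missing values as NaN, ages only if present)."""
    recs = [
        {
            "subject_id": r.subject_id, "eye": r.eye.value,
            "best_vision_sphere_d": r.best_vision_sphere, "bcva_logmar": r.bcva,
            "oms_db": np.nan if r.oms is None else r.oms,
            "v_tot_dbsr": np.nan if r.v_tot is None else r.v_tot,
            "age_years": np.nan if r.age is None else r.age,
        }
        for r in rows
    ]
    df = pd.DataFrame(recs)
    if df["age_years"].isna().all():
        df = df.drop(columns=["age_years"])
    return df


def read_cohort_table(path: str | Path) -> list[CohortRow]:
    """Read a Table-1-style cohort CSV.  Empty OMS/Vtot cells parse as missing."""
    try:
        df = pd.read_csv(path, dtype={"subject_id": str})
    except pd.errors.EmptyDataError as exc:
        raise ExamFormatError(f"{path}: empty cohort file") from exc
    missing = set(_COHORT_COLUMNS) - set(df.columns)
    if missing:
        raise ExamFormatError(f"{path}: missing columns {sorted(missing)}")
    rows: list[CohortRow] = []
    for i, r in df.iterrows():
        where = f"{path}: row {i + 2}"
        try:
            def num(col: str, required: bool = True) -> float | None:
                v = r.get(col, np.nan)
                if pd.isna(v) or (isinstance(v, str) and not v.strip()):
                    if required:
                        raise ExamFormatError(f"{where}: missing value in {col}")
                    return None
                out = float(v)
                if not np.isfinite(out):
                    raise ExamFormatError(f"{where}: non-finite value in {col}")
                return out

            rows.append(
                CohortRow(
                    subject_id=str(r["subject_id"]), eye=Eye(str(r["eye"])),
                    best_vision_sphere=num("best_vision_sphere_d"),
                    bcva=num("bcva_logmar"),
                    oms=num("oms_db", required=False),
                    v_tot=num("v_tot_dbsr", required=False),
                    age=num("age_years", required=False) if "age_years" in df.columns else None,
                )
            )
        except (ValueError, TypeError) as exc:
            raise ExamFormatError(f"{where}: malformed numeric cell ({exc})") from exc
    return rows
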