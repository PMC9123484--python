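"""Mean-sensitivity metrics: overall, subfield and hemifield means, cohort
summaries, and the age-vs-sensitivity logarithmic regression.

Averaging happens on the decibel scale throughout.  The overall mean
sensitivity (OMS) is the arithmetic mean of pointwise dB thresholds across the
grid, matching the perimeter's standard output; subfield and hemifield means
default to the geometric mean of the pointwise dB values.  Both methods are
available behind an explicit ``method`` flag.  Blind-spot points measure no
retinal function and are excluded from every average.

Zero sensitivities and the geometric mean: the default policy is
zero-inclusive (any 0 dB point makes the geometric mean 0); an explicit
``zeros="exclude"`` policy drops floor points instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .grid import Eye, Subfield, TestingGrid, hemifield_masks, subfield_mask
from .io import CohortRow, ExamRecord, cohort_to_frame

__all__ = [
    "overall_mean_sensitivity",
    "subfield_mean",
    "geometric_mean",
    "hemifield_comparison",
    "HemifieldComparison",
    "cohort_summary",
    "age_log_regression",
    "LogRegressionResult",
]


def _values(exam: "ExamRecord | np.ndarray") -> np.ndarray:
    v = exam.sensitivities if isinstance(exam, ExamRecord) else np.asarray(exam, float)
    return v


def geometric_mean(values: np.ndarray, zeros: str = "include") -> float:
    """Geometric mean of non-negative dB values.

    ``zeros="include"`` (default): any zero yields 0.  ``zeros="exclude"``:
    zeros are dropped first; if every value is zero the result is 0.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("geometric mean of an empty set")
    if np.any(v < 0):
        raise ValueError("geometric mean requires non-negative values")
    if zeros == "include":
        if np.any(v == 0):
            return 0.0
    elif zeros == "exclude":
        v = v[v > 0]
        if v.size == 0:
            return 0.0
    else:
        raise ValueError(f"unknown zero policy: {zeros!r}")
    return float(np.exp(np.mean(np.log(v))))


def overall_mean_sensitivity(exam: ExamRecord | np.ndarray, grid: TestingGrid) -> float:
    """Arithmetic mean of dB sensitivities over all non-blind-spot points."""
    v = _values(exam)
    if len(v) != grid.n_points:
        raise ValueError(
            f"exam has {len(v)} sensitivities but grid has {grid.n_points} points"
        )
    return float(np.mean(v[~grid.is_blind_spot]))


def subfield_mean(
    exam: ExamRecord | np.ndarray,
    grid: TestingGrid,
    subfield: Subfield | str,
    method: str = "geometric",
    zeros: str = "include",
) -> float:
    """Mean sensitivity of one subfield (blind-spot points excluded).

    ``method="geometric"`` (default, matching the subfield convention) or
    ``"arithmetic"``.
    """
    v = _values(exam)
    if len(v) != grid.n_points:
        raise ValueError("exam/grid size mismatch")
    mask = subfield_mask(grid, subfield) & ~grid.is_blind_spot
    if not mask.any():
        raise ValueError(f"empty subfield mask: {subfield}")
    vals = v[mask]
    if method == "geometric":
        return geometric_mean(vals, zeros=zeros)
    if method == "arithmetic":
        return float(np.mean(vals))
    raise ValueError(f"unknown averaging method: {method!r}")


@dataclass(frozen=True)
class HemifieldComparison:
    """Central nasal-vs-temporal hemifield comparison for one eye.

    ``mean_diff`` is temporal minus nasal, in dB, averaged over subjects;
    the paired t-test is two-sided on the per-subject hemifield means.
    ``composite_*`` are the geometric means, over each 47-point hemifield
    mask, of the cohort-averaged pointwise sensitivities (composite-map
    convention).
    """

    n_subjects: int
    n_points_per_hemifield: int
    mean_diff: float
    sd: float
    sem: float
    t_statistic: float
    p_value: float
    composite_nasal: float
    composite_temporal: float
    per_subject: pd.DataFrame


def hemifield_comparison(
    fields: Mapping[str, np.ndarray] | Sequence[ExamRecord],
    grid: TestingGrid,
    method: str = "geometric",
    zeros: str = "exclude",
) -> HemifieldComparison:
    """Compare central temporal vs nasal hemifield sensitivity across subjects.

    ``fields`` maps subject id -> full-grid sensitivities (one field per
    subject, e.g. that subject's reference test), or is a sequence of
    :class:`ExamRecord` (one per subject).

    Per-subject hemifield values use ``method`` over the 47-point masks
    (default geometric with zero-exclusion, so a partly floored hemifield
    remains finite); the difference is temporal minus nasal.  Requires at
    least two subjects.
    """
    if not isinstance(fields, Mapping):
        fields = {e.subject_id: e.sensitivities for e in fields}
    if len(fields) < 2:
        raise ValueError("hemifield comparison needs at least 2 subjects")
    nasal, temporal = hemifield_masks(grid)
    if nasal.sum() != temporal.sum():
        raise ValueError("unbalanced hemifield masks")

    def hemi(vals: np.ndarray, mask: np.ndarray) -> float:
        if method == "geometric":
            return geometric_mean(vals[mask], zeros=zeros)
        if method == "arithmetic":
            return float(np.mean(vals[mask]))
        raise ValueError(f"unknown averaging method: {method!r}")

    rows = []
    for subj, vals in fields.items():
        vals = np.asarray(vals, float)
        if len(vals) != grid.n_points:
            raise ValueError(f"subject {subj}: field/grid size mismatch")
        rows.append(
            {
                "subject_id": subj,
                "nasal": hemi(vals, nasal),
                "temporal": hemi(vals, temporal),
            }
        )
    per_subject = pd.DataFrame(rows)
    per_subject["diff"] = per_subject["temporal"] - per_subject["nasal"]
    diffs = per_subject["diff"].to_numpy()
    t, p = stats.ttest_rel(per_subject["temporal"], per_subject["nasal"])
    mean_field = np.mean(np.stack([np.asarray(v, float) for v in fields.values()]), axis=0)
    return HemifieldComparison(
        n_subjects=len(per_subject),
        n_points_per_hemifield=int(nasal.sum()),
        mean_diff=float(np.mean(diffs)),
        sd=float(np.std(diffs, ddof=1)),
        sem=float(np.std(diffs, ddof=1) / np.sqrt(len(diffs))),
        t_statistic=float(t),
        p_value=float(p),
        composite_nasal=geometric_mean(mean_field[nasal], zeros=zeros),
        composite_temporal=geometric_mean(mean_field[temporal], zeros=zeros),
        per_subject=per_subject,
    )


_SUMMARY_VARS = {
    "bcva_logmar": "BCVA (logMAR)",
    "best_vision_sphere_d": "Best vision sphere (D)",
    "oms_db": "Overall mean sensitivity (dB)",
    "v_tot_dbsr": "Total volume (dB-sr)",
}


def cohort_summary(rows: "Sequence[CohortRow] | pd.DataFrame") -> pd.DataFrame:
    """Per-eye mean/SD/range of BCVA, refraction and OMS (sample SD, n-1).

    Missing values are skipped with the contributing ``n`` reported; a
    single-value SD is reported as NaN (flagged undefined rather than 0).
    """
    df = rows if isinstance(rows, pd.DataFrame) else cohort_to_frame(rows)
    if len(df) == 0:
        raise ValueError("empty cohort table")
    out = []
    for eye, g in df.groupby("eye"):
        for col, label in _SUMMARY_VARS.items():
            if col not in g.columns:
                continue
            v = g[col].dropna().to_numpy(float)
            if v.size == 0:
                continue
            out.append(
                {
                    "eye": eye,
                    "measure": label,
                    "n": int(v.size),
                    "mean": float(np.mean(v)),
                    "sd": float(np.std(v, ddof=1)) if v.size > 1 else np.nan,
                    "min": float(np.min(v)),
                    "max": float(np.max(v)),
                }
            )
    return pd.DataFrame(out)


@dataclass(frozen=True)
class LogRegressionResult:
    """OLS fit of a response on ln(age)."""

    slope: float
    intercept: float
    r_squared: float
    p_value: float
    stderr_slope: float
    n: int

    def predict(self, ages: np.ndarray) -> np.ndarray:
        return self.intercept + self.slope * np.log(np.asarray(ages, float))


def age_log_regression(ages: np.ndarray, values: np.ndarray) -> LogRegressionResult:
    """Ordinary least squares of a sensitivity measure on ln(age in years).

    Returns the slope (units per ln-year), intercept, Pearson r-squared and
    the two-sided p-value for the slope.  Pairs with a missing value are
    dropped; requires n >= 3, positive ages and non-constant ln(age).
    """
    ages = np.asarray(ages, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(ages) != len(values):
        raise ValueError("ages and values must be paired")
    keep = np.isfinite(ages) & np.isfinite(values)
    ages, values = ages[keep], values[keep]
    if len(ages) < 3:
        raise ValueError("logarithmic regression needs at least 3 complete pairs")
    if np.any(ages <= 0):
        raise ValueError("ages must be positive")
    la = np.log(ages)
    if np.ptp(la) == 0:
        raise ValueError("zero variance in ln(age)")
    if np.ptp(values) == 0:
        # constant response: flat fit, no explained variance
        return LogRegressionResult(
            slope=0.0, intercept=float(values[0]), r_squared=0.0,
            p_value=1.0, stderr_slope=0.0, n=len(ages),
        )
    res = stats.linregress(la, values)
    return LogRegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
        stderr_slope=float(res.stderr),
        n=len(ages),
    )
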