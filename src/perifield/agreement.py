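"""Bland-Altman repeatability, interocular symmetry and related statistics.

Test-retest agreement follows Bland and Altman: for paired measurements the
mean difference, its sample SD (n-1), the 95% limits of agreement
(mean +/- 1.96 SD) and the coefficient of repeatability (CoR = 1.96 SD, i.e.
half the width of the limits of agreement).  The 1.96 multiplier is fixed (no
small-sample t correction).  Differences are taken as second minus first
(later test minus earlier test).

Pointwise repeatability handles the 0 dB floor: with floor exclusion on
(default), a grid point contributes a pair only when both tests measured
above 0 dB, removing pairs whose variability is censored by the floor.

Interocular symmetry is a bivariate correlation gated on normality:
Shapiro-Wilk on each eye's values, Pearson when both pass, Spearman's rho
when either fails.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .grid import TestingGrid
from .io import ExamRecord, RF_THRESHOLD

__all__ = [
    "AgreementResult",
    "SymmetryResult",
    "bland_altman",
    "agreement_from_differences",
    "pointwise_repeatability",
    "pooled_pointwise_differences",
    "interocular_symmetry",
    "bonferroni_alpha",
    "min_detectable_interval",
    "mean_interocular_difference",
    "select_reference_test",
    "consecutive_reliable_pairs",
]

LOA_MULTIPLIER = 1.96


@dataclass(frozen=True)
class AgreementResult:
    """Bland-Altman agreement summary.

    Invariants: ``loa_lower = mean_diff - 1.96*sd_diff``,
    ``loa_upper = mean_diff + 1.96*sd_diff``,
    ``cor = 1.96*sd_diff = (loa_upper - loa_lower)/2``.
    """

    n_pairs: int
    mean_diff: float
    sd_diff: float
    loa_lower: float
    loa_upper: float
    cor: float


def agreement_from_differences(diffs: np.ndarray) -> AgreementResult:
    """Bland-Altman summary from raw paired differences (second - first)."""
    diffs = np.asarray(diffs, dtype=float)
    if diffs.size < 2:
        raise ValueError("Bland-Altman needs at least 2 pairs")
    mean = float(np.mean(diffs))
    sd = float(np.std(diffs, ddof=1))
    return AgreementResult(
        n_pairs=int(diffs.size),
        mean_diff=mean,
        sd_diff=sd,
        loa_lower=mean - LOA_MULTIPLIER * sd,
        loa_upper=mean + LOA_MULTIPLIER * sd,
        cor=LOA_MULTIPLIER * sd,
    )


def bland_altman(pairs: Iterable[tuple[float, float]]) -> AgreementResult:
    """Bland-Altman agreement for (first, second) measurement pairs."""
    arr = np.asarray(list(pairs), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("pairs must be (first, second) tuples")
    return agreement_from_differences(arr[:, 1] - arr[:, 0])


def pointwise_repeatability(
    exam_a: ExamRecord | np.ndarray,
    exam_b: ExamRecord | np.ndarray,
    grid: TestingGrid | None = None,
    floor_exclude: bool = True,
) -> AgreementResult:
    """Pointwise Bland-Altman between two tests of the same eye.

    Differences are ``exam_b - exam_a`` per grid point.  Blind-spot points
    are dropped when a grid is supplied.  With ``floor_exclude`` a point
    contributes only if both tests measured strictly above 0 dB.
    """
    a = exam_a.sensitivities if isinstance(exam_a, ExamRecord) else np.asarray(exam_a, float)
    b = exam_b.sensitivities if isinstance(exam_b, ExamRecord) else np.asarray(exam_b, float)
    if isinstance(exam_a, ExamRecord) and isinstance(exam_b, ExamRecord):
        if (exam_a.subject_id, exam_a.eye) != (exam_b.subject_id, exam_b.eye):
            raise ValueError("pointwise repeatability requires the same subject and eye")
    if a.shape != b.shape:
        raise ValueError("exams must share the same grid")
    keep = np.ones(len(a), dtype=bool)
    if grid is not None:
        if len(a) != grid.n_points:
            raise ValueError("exam/grid size mismatch")
        keep &= ~grid.is_blind_spot
    if floor_exclude:
        keep &= (a > 0) & (b > 0)
    if keep.sum() < 2:
        raise ValueError("no surviving point pairs after exclusions")
    return agreement_from_differences(b[keep] - a[keep])


def pooled_pointwise_differences(
    exams: Sequence[ExamRecord],
    grid: TestingGrid,
    pair: tuple[int, int] = (2, 3),
    floor_exclude: bool = True,
) -> AgreementResult:
    """Pointwise repeatability pooled over every eye with both tests of ``pair``.

    Differences are later minus earlier, concatenated across subjects and
    eyes before the Bland-Altman summary.
    """
    first_idx, second_idx = pair
    by_key: dict[tuple[str, str], dict[int, ExamRecord]] = {}
    for e in exams:
        by_key.setdefault((e.subject_id, e.eye.value), {})[e.test_index] = e
    diffs: list[np.ndarray] = []
    for tests in by_key.values():
        if first_idx in tests and second_idx in tests:
            a = tests[first_idx].sensitivities
            b = tests[second_idx].sensitivities
            keep = ~grid.is_blind_spot
            if floor_exclude:
                keep &= (a > 0) & (b > 0)
            diffs.append(b[keep] - a[keep])
    if not diffs:
        raise ValueError(f"no eye has both tests {first_idx} and {second_idx}")
    return agreement_from_differences(np.concatenate(diffs))


@dataclass(frozen=True)
class SymmetryResult:
    """Interocular correlation with Shapiro-Wilk normality gating."""

    measure: str
    n: int
    normality_p_od: float
    normality_p_os: float
    method: str  # "pearson" | "spearman"
    coefficient: float
    p_value: float
    bonferroni_alpha: float | None = None


def interocular_symmetry(
    values_od: np.ndarray,
    values_os: np.ndarray,
    alpha_normality: float = 0.05,
    measure: str = "",
    bonferroni_m: int | None = None,
) -> SymmetryResult:
    """Right-vs-left-eye correlation of a per-subject measure.

    Subjects with either eye missing are dropped pairwise.  Shapiro-Wilk is
    run per eye; Pearson's r is used when both eyes pass at
    ``alpha_normality``, otherwise Spearman's rho (the conservative
    either-eye-fails rule).
    """
    od = np.asarray(values_od, dtype=float)
    os_ = np.asarray(values_os, dtype=float)
    if od.shape != os_.shape:
        raise ValueError("eyes must be paired by subject")
    keep = np.isfinite(od) & np.isfinite(os_)
    od, os_ = od[keep], os_[keep]
    n = len(od)
    if n < 3:
        raise ValueError("interocular symmetry needs at least 3 complete pairs")
    if np.ptp(od) == 0 or np.ptp(os_) == 0:
        raise ValueError("correlation undefined for a constant eye")
    p_od = float(stats.shapiro(od).pvalue)
    p_os = float(stats.shapiro(os_).pvalue)
    if p_od >= alpha_normality and p_os >= alpha_normality:
        r, p = stats.pearsonr(od, os_)
        method = "pearson"
    else:
        r, p = stats.spearmanr(od, os_)
        method = "spearman"
    return SymmetryResult(
        measure=measure,
        n=n,
        normality_p_od=p_od,
        normality_p_os=p_os,
        method=method,
        coefficient=float(r),
        p_value=float(p),
        bonferroni_alpha=None if bonferroni_m is None
        else bonferroni_alpha(m_comparisons=bonferroni_m),
    )


def bonferroni_alpha(alpha: float = 0.05, m_comparisons: int = 1) -> float:
    """Bonferroni-adjusted per-comparison significance level alpha / m."""
    if m_comparisons < 1:
        raise ValueError("number of comparisons must be >= 1")
    return alpha / m_comparisons


def min_detectable_interval(cor: float, annual_decline: float) -> float:
    """Minimum follow-up interval (years) to detect true change.

    A change is distinguishable from test-retest noise once the expected
    decline exceeds the coefficient of repeatability: interval = CoR /
    annual decline rate.
    """
    if annual_decline <= 0:
        raise ValueError("annual decline must be positive")
    if cor < 0:
        raise ValueError("coefficient of repeatability must be >= 0")
    return cor / annual_decline


def mean_interocular_difference(
    values_od: np.ndarray, values_os: np.ndarray
) -> tuple[float, float]:
    """Mean and SD of the absolute interocular difference |OD - OS|.

    Subjects with either eye missing are dropped pairwise.
    """
    od = np.asarray(values_od, dtype=float)
    os_ = np.asarray(values_os, dtype=float)
    if od.shape != os_.shape:
        raise ValueError("eyes must be paired by subject")
    keep = np.isfinite(od) & np.isfinite(os_)
    d = np.abs(od[keep] - os_[keep])
    if d.size == 0:
        raise ValueError("no complete interocular pairs")
    sd = float(np.std(d, ddof=1)) if d.size > 1 else float("nan")
    return float(np.mean(d)), sd


def select_reference_test(
    exams: Sequence[ExamRecord], threshold: float = RF_THRESHOLD
) -> ExamRecord | None:
    """Reference test for one eye: the latest reliable test (3, else 2, else 1).

    Returns None when no test is reliable.
    """
    reliable = [e for e in exams if e.reliability_factor <= threshold]
    if not reliable:
        return None
    return max(reliable, key=lambda e: e.test_index)


def consecutive_reliable_pairs(
    exams: Sequence[ExamRecord], threshold: float = RF_THRESHOLD
) -> list[tuple[ExamRecord, ExamRecord]]:
    """Consecutive test pairs (1,2) and (2,3) where both members are reliable."""
    by_idx = {e.test_index: e for e in exams if e.reliability_factor <= threshold}
    out = []
    for a, b in ((1, 2), (2, 3)):
        if a in by_idx and b in by_idx:
            out.append((by_idx[a], by_idx[b]))
    return out
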