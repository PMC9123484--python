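"""Cohort-level analysis model: the full pipeline behind one `fit()` call.

:class:`WidefieldPerimetry` is built from exam records (plus an optional
Table-1-style cohort frame) and orchestrates the analysis stages in order:
reliability filtering -> per-eye reference values and summaries -> hill-of-
vision volumes -> test-retest repeatability -> interocular symmetry ->
central hemifield asymmetry (-> age regression when ages are available).
:meth:`WidefieldPerimetry.fit` returns a :class:`WidefieldPerimetryResults`
carrying the tables, which renders them with :meth:`~WidefieldPerimetryResults.summary`.

Every number in the results is reproducible by re-running the stage
functions on the same inputs; the model adds bookkeeping (reference-test
selection, pairwise pairing, exclusion audit), not statistics of its own.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import agreement as agr
from . import metrics
from .grid import Eye, Subfield, TestingGrid, build_grid
from .hill import hill_of_vision, subfield_fractions, interpolate_field
from .io import ExamRecord, RF_THRESHOLD, read_cohort_table, read_exams, cohort_to_frame

__all__ = ["WidefieldPerimetry", "WidefieldPerimetryResults", "NoReliableTestsError"]

_SUBFIELD_LABEL = {
    Subfield.CENTRAL30: "Central 30 degrees MS (dB)",
    Subfield.INFEROTEMPORAL: "Inferior temporal MS (dB)",
    Subfield.SUPEROTEMPORAL: "Superior temporal MS (dB)",
    Subfield.INFERONASAL: "Inferior nasal MS (dB)",
    Subfield.SUPERONASAL: "Superior nasal MS (dB)",
}


class NoReliableTestsError(RuntimeError):
    """Raised when the reliability filter leaves no analysable exams."""


@dataclass
class WidefieldPerimetryResults:
    """Fitted cohort analysis: tables, agreement results and audit trail."""

    model: "WidefieldPerimetry"
    n_exams: int
    n_excluded: int
    exclusion_log: pd.DataFrame
    eye_values: pd.DataFrame          # per subject/eye reference-test measures
    cohort_summary: pd.DataFrame
    symmetry_table: pd.DataFrame
    symmetry_results: dict[str, agr.SymmetryResult]
    repeatability_table: pd.DataFrame
    repeatability_results: dict[tuple[str, str, str], agr.AgreementResult]
    hemifield: dict[str, metrics.HemifieldComparison]
    age_regression: dict[str, metrics.LogRegressionResult]

    def min_detectable_interval(
        self, annual_decline: float, measure: str = "Overall mean sensitivity (dB)",
        eye: str = "OD", pair: str = "test3-test2",
    ) -> float:
        """Years of follow-up needed for true change to exceed the CoR."""
        cor = self.repeatability_results[(measure, eye, pair)].cor
        return agr.min_detectable_interval(cor, annual_decline)

    def tables(self) -> dict[str, pd.DataFrame]:
        return {
            "cohort_summary": self.cohort_summary,
            "eye_values": self.eye_values,
            "symmetry": self.symmetry_table,
            "repeatability": self.repeatability_table,
            "exclusions": self.exclusion_log,
        }

    def save_tables(self, outdir: str | Path) -> list[Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        written = []
        for name, df in self.tables().items():
            p = outdir / f"{name}.csv"
            df.to_csv(p, index=False)
            written.append(p)
        return written

    def summary(self, float_format: str = "%.3f") -> str:
        """Human-readable report of every fitted table."""
        pd.set_option("display.width", 120)
        lines = [
            "Wide-field static perimetry cohort analysis",
            "=" * 60,
            f"Exams analysed: {self.n_exams} "
            f"(excluded as unreliable: {self.n_excluded})",
            "",
            "Cohort summary (per eye)",
            "-" * 60,
            self.cohort_summary.to_string(index=False, float_format=lambda v: float_format % v),
            "",
            "Interocular symmetry",
            "-" * 60,
            self.symmetry_table.to_string(index=False, float_format=lambda v: float_format % v),
        ]
        if len(self.repeatability_table):
            lines += [
                "",
                "Test-retest repeatability (Bland-Altman)",
                "-" * 60,
                self.repeatability_table.to_string(index=False, float_format=lambda v: float_format % v),
            ]
        for eye, hc in self.hemifield.items():
            lines += [
                "",
                f"Central hemifield asymmetry, {eye} (temporal - nasal, "
                f"{hc.n_points_per_hemifield} points/hemifield): "
                f"{hc.mean_diff:.2f} dB (SD {hc.sd:.2f}, SEM {hc.sem:.2f}), "
                f"paired t p = {hc.p_value:.3g}",
            ]
        for eye, reg in self.age_regression.items():
            lines += [
                f"OMS vs ln(age), {eye}: slope {reg.slope:.2f} dB/ln-year, "
                f"r^2 = {reg.r_squared:.2f}, p = {reg.p_value:.3g} (n = {reg.n})",
            ]
        return "\n".join(lines)


class WidefieldPerimetry:
    """Wide-field perimetry cohort model.

    Parameters
    ----------
    exams:
        All exam records of the cohort (triplicate tests, both eyes).
    cohort:
        Optional Table-1-style frame (acuity, refraction, optionally age);
        when absent, summaries cover the exam-derived measures only.
    rf_threshold:
        Reliability-factor exclusion threshold (exclude strictly above).
    resolution_deg:
        Raster resolution for hill-of-vision volumes.
    """

    def __init__(
        self,
        exams: Sequence[ExamRecord],
        cohort: pd.DataFrame | None = None,
        rf_threshold: float = RF_THRESHOLD,
        resolution_deg: float = 0.5,
    ) -> None:
        if len(exams) == 0:
            raise ValueError("no exams supplied")
        self.exams = list(exams)
        self.cohort = cohort
        self.rf_threshold = rf_threshold
        self.resolution_deg = resolution_deg
        self.grids = {Eye.OD: build_grid(Eye.OD), Eye.OS: build_grid(Eye.OS)}

    @classmethod
    def from_csv(
        cls, exam_path: str | Path, cohort_path: str | Path | None = None, **kwargs
    ) -> "WidefieldPerimetry":
        cohort = None
        if cohort_path is not None:
            cohort = cohort_to_frame(read_cohort_table(cohort_path))
        return cls(read_exams(exam_path), cohort=cohort, **kwargs)

    # -- helpers --------------------------------------------------------------
    def _grouped(self) -> dict[tuple[str, Eye], list[ExamRecord]]:
        by: dict[tuple[str, Eye], list[ExamRecord]] = {}
        for e in self.exams:
            by.setdefault((e.subject_id, e.eye), []).append(e)
        return by

    def _eye_measures(
        self, exam: ExamRecord, grid: TestingGrid,
        fractions: Mapping[Subfield, np.ndarray] | None,
        compute_volumes: bool,
    ) -> dict[str, float]:
        out = {
            "Overall MS (dB)": metrics.overall_mean_sensitivity(exam, grid),
        }
        # geometric subfield means with floor (0 dB) points dropped: a single
        # floored point would otherwise zero out the whole subfield
        for sf, label in _SUBFIELD_LABEL.items():
            out[label] = metrics.subfield_mean(
                exam, grid, sf, method="geometric", zeros="exclude"
            )
        if compute_volumes:
            hov = hill_of_vision(exam, grid, self.resolution_deg, fractions=fractions)
            out["Vtot (dB-sr)"] = hov.v_tot
            out["V30 (dB-sr)"] = hov.v_30
            out["V inferotemporal (dB-sr)"] = hov.v_subfield[Subfield.INFEROTEMPORAL]
        return out

    # -- fitting --------------------------------------------------------------
    def fit(self, compute_volumes: bool = True) -> WidefieldPerimetryResults:
        """Run the pipeline and return the fitted results."""
        kept = [e for e in self.exams if e.reliability_factor <= self.rf_threshold]
        excluded = [e for e in self.exams if e.reliability_factor > self.rf_threshold]
        exclusion_log = pd.DataFrame(
            [
                {
                    "subject_id": e.subject_id, "eye": e.eye.value,
                    "test_index": e.test_index,
                    "reliability_factor": e.reliability_factor,
                    "reason": f"RF > {self.rf_threshold:.0%}",
                }
                for e in excluded
            ],
            columns=["subject_id", "eye", "test_index", "reliability_factor", "reason"],
        )
        if not kept:
            raise NoReliableTestsError(
                "no reliable tests: every exam exceeded the reliability threshold"
            )

        fractions = {
            eye: subfield_fractions(
                interpolate_field(np.zeros(g.n_points), g, self.resolution_deg), eye
            )
            for eye, g in self.grids.items()
        } if compute_volumes else {Eye.OD: None, Eye.OS: None}

        measure_cache: dict[tuple[str, str, int], dict[str, float]] = {}

        def exam_measures(exam: ExamRecord) -> dict[str, float]:
            key = exam.key
            if key not in measure_cache:
                measure_cache[key] = self._eye_measures(
                    exam, self.grids[exam.eye], fractions[exam.eye], compute_volumes
                )
            return measure_cache[key]

        # reference-test measures per eye
        grouped = self._grouped()
        rows = []
        ref_fields: dict[Eye, dict[str, np.ndarray]] = {Eye.OD: {}, Eye.OS: {}}
        for (subj, eye), eye_exams in sorted(grouped.items(), key=lambda kv: (kv[0][0], kv[0][1].value)):
            ref = agr.select_reference_test(eye_exams, self.rf_threshold)
            row: dict[str, object] = {"subject_id": subj, "eye": eye.value}
            if ref is not None:
                row["reference_test"] = ref.test_index
                row.update(exam_measures(ref))
                ref_fields[eye][subj] = ref.sensitivities
            rows.append(row)
        eye_values = pd.DataFrame(rows)

        # cohort summary (exam-derived OMS + any provided cohort columns)
        summary_frames = []
        if self.cohort is not None:
            summary_frames.append(metrics.cohort_summary(self.cohort))
        oms_frame = eye_values.rename(columns={"Overall MS (dB)": "oms_db"})[
            ["subject_id", "eye", "oms_db"]
        ]
        if self.cohort is None or "oms_db" not in self.cohort.columns:
            synth = oms_frame.assign(bcva_logmar=np.nan, best_vision_sphere_d=np.nan)
            summary_frames.append(metrics.cohort_summary(synth))
        cohort_summary = pd.concat(summary_frames, ignore_index=True)

        # interocular symmetry on the reference-test measures
        measure_cols = [c for c in eye_values.columns
                        if c not in ("subject_id", "eye", "reference_test")]
        od = eye_values[eye_values["eye"] == "OD"].set_index("subject_id")
        os_ = eye_values[eye_values["eye"] == "OS"].set_index("subject_id")
        subjects = sorted(set(od.index) | set(os_.index))
        sym_rows, sym_results = [], {}
        ms_measures = [c for c in measure_cols if "(dB)" in c]
        m_corr = max(len(ms_measures) - 1, 1)  # subfield comparisons vs overall
        for col in measure_cols:
            a = od[col].reindex(subjects).to_numpy(float) if col in od else np.full(len(subjects), np.nan)
            b = os_[col].reindex(subjects).to_numpy(float) if col in os_ else np.full(len(subjects), np.nan)
            try:
                res = agr.interocular_symmetry(a, b, measure=col, bonferroni_m=m_corr)
                mean_ad, sd_ad = agr.mean_interocular_difference(a, b)
            except ValueError:
                continue
            sym_results[col] = res
            ok = np.isfinite(a) & np.isfinite(b)
            sym_rows.append(
                {
                    "measure": col, "n": res.n,
                    "od_mean": float(np.mean(a[ok])), "od_sd": float(np.std(a[ok], ddof=1)),
                    "os_mean": float(np.mean(b[ok])), "os_sd": float(np.std(b[ok], ddof=1)),
                    "mean_interocular_diff": mean_ad, "diff_sd": sd_ad,
                    "method": res.method, "coefficient": res.coefficient,
                    "p_value": res.p_value,
                    "shapiro_p_od": res.normality_p_od, "shapiro_p_os": res.normality_p_os,
                }
            )
        symmetry_table = pd.DataFrame(sym_rows)

        # test-retest repeatability per eye and consecutive pair
        rep_rows, rep_results = [], {}
        for eye in (Eye.OD, Eye.OS):
            grid = self.grids[eye]
            pair_diffs: dict[tuple[int, int], dict[str, list[float]]] = {}
            pw: dict[tuple[int, int], list[np.ndarray]] = {}
            for (subj, e_eye), eye_exams in grouped.items():
                if e_eye is not eye:
                    continue
                for first, second in agr.consecutive_reliable_pairs(eye_exams, self.rf_threshold):
                    key = (first.test_index, second.test_index)
                    m1 = exam_measures(first)
                    m2 = exam_measures(second)
                    d = pair_diffs.setdefault(key, {})
                    for col in m1:
                        d.setdefault(col, []).append(m2[col] - m1[col])
                    keep = ~grid.is_blind_spot & (first.sensitivities > 0) & (second.sensitivities > 0)
                    pw.setdefault(key, []).append(
                        second.sensitivities[keep] - first.sensitivities[keep]
                    )
            for (i, j), cols in sorted(pair_diffs.items()):
                pair_name = f"test{j}-test{i}"
                for col, diffs in cols.items():
                    if len(diffs) < 2:
                        continue
                    res = agr.agreement_from_differences(np.asarray(diffs))
                    rep_results[(col, eye.value, pair_name)] = res
                    rep_rows.append(
                        {
                            "measure": col, "eye": eye.value, "pair": pair_name,
                            "n_pairs": res.n_pairs, "mean_diff": res.mean_diff,
                            "cor": res.cor, "loa_lower": res.loa_lower,
                            "loa_upper": res.loa_upper,
                        }
                    )
                if (i, j) in pw and pw[(i, j)]:
                    res = agr.agreement_from_differences(np.concatenate(pw[(i, j)]))
                    col = "Pointwise sensitivity (dB)"
                    rep_results[(col, eye.value, pair_name)] = res
                    rep_rows.append(
                        {
                            "measure": col, "eye": eye.value, "pair": pair_name,
                            "n_pairs": res.n_pairs, "mean_diff": res.mean_diff,
                            "cor": res.cor, "loa_lower": res.loa_lower,
                            "loa_upper": res.loa_upper,
                        }
                    )
        repeatability_table = pd.DataFrame(
            rep_rows,
            columns=["measure", "eye", "pair", "n_pairs", "mean_diff", "cor",
                     "loa_lower", "loa_upper"],
        )

        # central hemifield asymmetry
        hemifield = {}
        for eye in (Eye.OD, Eye.OS):
            if len(ref_fields[eye]) >= 2:
                hemifield[eye.value] = metrics.hemifield_comparison(
                    ref_fields[eye], self.grids[eye]
                )

        # OMS-vs-age regression when ages are available
        age_regression = {}
        if self.cohort is not None and "age_years" in self.cohort.columns:
            merged = oms_frame.merge(
                self.cohort[["subject_id", "eye", "age_years"]], on=["subject_id", "eye"]
            )
            for eye, g in merged.groupby("eye"):
                try:
                    age_regression[str(eye)] = metrics.age_log_regression(
                        g["age_years"], g["oms_db"]
                    )
                except ValueError:
                    pass

        return WidefieldPerimetryResults(
            model=self,
            n_exams=len(kept),
            n_excluded=len(excluded),
            exclusion_log=exclusion_log,
            eye_values=eye_values,
            cohort_summary=cohort_summary,
            symmetry_table=symmetry_table,
            symmetry_results=sym_results,
            repeatability_table=repeatability_table,
            repeatability_results=rep_results,
            hemifield=hemifield,
            age_regression=age_regression,
        )
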