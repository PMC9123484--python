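"""Synthetic bilateral triplicate-test perimetry cohorts.

The generator emulates the statistical structure that the analysis pipeline
assumes for an X-linked rod-cone dystrophy cohort: a preserved central island
and a preserved inferotemporal island riding on near-floor nasal quadrants,
overall sensitivity declining logarithmically with age, strong interocular
symmetry, and triplicate testing with pointwise test-retest noise plus a
first-test learning effect.

Construction per subject (all on the dB scale):

1.  A latent overall mean sensitivity (OMS) target
    ``intercept + slope * ln(age) + N(0, resid_sd)``.
2.  A fixed non-negative reference profile ``P`` over the grid — central
    Gaussian island + inferotemporal Gaussian island + constant nasal floor,
    0 at the blind spot — scaled per subject so that the latent OMS equals
    the target exactly.  The inferotemporal island amplitude is solved in
    closed form so the across-subject regression slope of the inferotemporal
    on the central arithmetic subfield mean equals the configured coupling
    (default 1).
3.  A constant temporal offset added to the 47 central temporal-hemifield
    points (nasal-temporal asymmetry).
4.  The left eye mirrors the right with an eye-level OMS perturbation
    (interocular noise).
5.  Three tests: per-test global shift + i.i.d. per-point noise, test 1
    additionally degraded by the learning offset and extra noise; values
    clipped to [floor, ceiling].
6.  A reliability factor per test: a configurable forced-unreliable pattern
    (default reproduces a 60-exam cohort with 5 unreliable tests, 4 of them
    in one subject), others drawn from a scaled Beta so they stay reliable.

Randomness: a single master seed; subject-level draws come from the master
stream in a fixed documented order (ages, severity residuals, eye deltas,
refraction, acuity), then one spawned child stream per subject for test
noise and reliability draws.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .agreement import select_reference_test
from .grid import (
    CENTRAL_RADIUS_DEG as CENTRAL_RADIUS,
    Eye,
    Subfield,
    TestingGrid,
    build_grid,
    subfield_mask,
)
from .io import CohortRow, ExamRecord, read_cohort_table
from .metrics import overall_mean_sensitivity

__all__ = [
    "SyntheticConfig",
    "default_rpgr_config",
    "generate_cohort",
    "reference_profile",
    "expected_oms",
    "implied_interocular_r",
    "implied_pointwise_cor",
    "table1_fixture",
    "config_to_yaml",
    "config_from_yaml",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Generative parameters of the synthetic cohort.

    Units are dB, degrees and years.  ``decline_intercept`` and
    ``decline_log_slope`` describe the latent OMS age model
    ``OMS = intercept + slope * ln(age)``; island parameters describe the
    reference sensitivity profile at reference severity; noise SDs are on the
    dB scale.  ``unreliable_pattern`` lists (subject number 1-based, eye,
    test index) triples forced to an unreliable reliability factor.
    """

    n_subjects: int = 10
    age_range: tuple[float, float] = (20.0, 49.0)
    decline_intercept: float = 38.6       # dB at ln(age) = 0
    decline_log_slope: float = -9.0       # dB per ln-year
    severity_resid_sd: float = 2.3        # between-subject scatter around the age trend
    central_peak: float = 14.0            # dB, reference central island peak
    central_sigma: float = 18.0           # deg
    it_center: tuple[float, float] = (45.0, -35.0)  # (temporal deg, vertical deg)
    it_sigma: float = 15.0                # deg
    it_coupling: float = 1.0              # inferotemporal-vs-central subfield-mean slope
    nasal_floor_level: float = 2.5        # dB, reference nasal-quadrant base
    temporal_offset: float = 2.0          # dB added to central temporal hemifield
    interocular_noise_sd: float = 0.5     # dB, eye-level OMS perturbation
    test_noise_sd: float = 1.5            # dB, i.i.d. per point per test
    test_global_sd: float = 0.3           # dB, shared across points within a test
    learning_offset_test1: float = 1.0    # dB degradation applied to test 1
    learning_extra_sd_test1: float = 1.0  # dB extra per-point noise on test 1
    rf_beta: tuple[float, float] = (2.0, 8.0)   # Beta shape for reliable RFs
    rf_catch_trials: int = 20
    unreliable_rf: float = 0.4
    unreliable_pattern: tuple[tuple[int, str, int], ...] = (
        (2, "OD", 1), (2, "OD", 2), (2, "OD", 3), (2, "OS", 3), (3, "OD", 3),
    )
    floor: float = 0.0                    # dB dynamic-range floor
    ceiling: float = 50.0                 # dB dynamic-range ceiling
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if not self.age_range[0] < self.age_range[1] or self.age_range[0] <= 0:
            raise ValueError("age_range must be an increasing positive interval")
        for name in ("severity_resid_sd", "interocular_noise_sd", "test_noise_sd",
                     "test_global_sd", "learning_extra_sd_test1"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.central_sigma <= 0 or self.it_sigma <= 0:
            raise ValueError("island radii must be positive")
        if not self.floor < self.ceiling:
            raise ValueError("floor must be below ceiling")
        if not 0 <= self.unreliable_rf <= 1:
            raise ValueError("unreliable_rf must be a fraction")


def default_rpgr_config(seed: int = 0) -> SyntheticConfig:
    """Default 10-subject cohort emulating a young-adult rod-cone dystrophy group."""
    return SyntheticConfig(seed=seed)


# --- reference profile -------------------------------------------------------

def _masks(grid: TestingGrid) -> dict[str, np.ndarray]:
    nb = ~grid.is_blind_spot
    return {
        "central": subfield_mask(grid, Subfield.CENTRAL30) & nb,
        "it": subfield_mask(grid, Subfield.INFEROTEMPORAL),
        "nasal": (subfield_mask(grid, Subfield.INFERONASAL)
                  | subfield_mask(grid, Subfield.SUPERONASAL)),
        "nonblind": nb,
        "temporal_central": subfield_mask(grid, Subfield.CENTRAL30) & nb
        & (grid.temporal_x > 0),
    }


def reference_profile(config: SyntheticConfig, grid: TestingGrid | None = None) -> np.ndarray:
    """Reference sensitivity profile ``P`` (dB) over the grid at unit severity.

    Anatomic coordinates are used, so the profile is identical per point id
    for OD and OS grids.  The inferotemporal amplitude is chosen so that the
    latent inferotemporal-vs-central arithmetic subfield-mean slope equals
    ``config.it_coupling`` exactly (closed form; severity scales the whole
    profile linearly).
    """
    if grid is None:
        grid = build_grid(Eye.OD)
    tx, y = grid.temporal_x, grid.y
    ecc = grid.eccentricity
    m = _masks(grid)

    g_c = np.exp(-(ecc**2) / (2.0 * config.central_sigma**2))
    d2 = (tx - config.it_center[0]) ** 2 + (y - config.it_center[1]) ** 2
    # peripheral island only: the drop across the 30-degree boundary mimics the
    # ring scotoma separating the central and peripheral islands, and keeps the
    # central latent field mirror-symmetric apart from the configured offset
    g_it = np.exp(-d2 / (2.0 * config.it_sigma**2)) * (ecc > CENTRAL_RADIUS)

    # closed-form inferotemporal amplitude for the configured coupling slope
    k = config.it_coupling
    m_c_IT, m_it_IT = g_c[m["it"]].mean(), g_it[m["it"]].mean()
    m_c_C, m_it_C = g_c[m["central"]].mean(), g_it[m["central"]].mean()
    denom = m_it_IT - k * m_it_C
    if denom <= 0:
        raise ValueError("inferotemporal island cannot realise the requested coupling")
    a_it = config.central_peak * (k * m_c_C - m_c_IT) / denom

    profile = config.central_peak * g_c + a_it * g_it
    profile[m["nasal"]] += config.nasal_floor_level
    profile[grid.is_blind_spot] = 0.0
    return profile


def expected_oms(config: SyntheticConfig, age: "float | np.ndarray") -> "float | np.ndarray":
    """Latent (noise-free) OMS implied by the age model."""
    return config.decline_intercept + config.decline_log_slope * np.log(age)


def _lnage_moments(config: SyntheticConfig) -> tuple[float, float]:
    """Mean and variance of ln(age) for the uniform age distribution."""
    lo, hi = config.age_range
    w = hi - lo
    m1 = (hi * np.log(hi) - lo * np.log(lo)) / w - 1.0
    m2 = (hi * (np.log(hi) ** 2 - 2 * np.log(hi) + 2)
          - lo * (np.log(lo) ** 2 - 2 * np.log(lo) + 2)) / w
    return m1, m2 - m1**2


def implied_interocular_r(config: SyntheticConfig, grid: TestingGrid | None = None) -> float:
    """Closed-form interocular Pearson correlation of single-test OMS.

    Variance components: between-subject latent OMS variance (age model +
    severity residual) is shared between the eyes; the eye-level perturbation
    and the single-test OMS noise (global shift + averaged point noise) are
    not.
    """
    if grid is None:
        grid = build_grid(Eye.OD)
    n_pts = int((~grid.is_blind_spot).sum())
    _, var_ln = _lnage_moments(config)
    var_between = config.decline_log_slope**2 * var_ln + config.severity_resid_sd**2
    var_test = config.test_global_sd**2 + config.test_noise_sd**2 / n_pts
    return var_between / (var_between + config.interocular_noise_sd**2 + var_test)


def implied_pointwise_cor(config: SyntheticConfig) -> float:
    """Config-implied pointwise coefficient of repeatability between tests 2 and 3.

    The test-retest SD of one point combines the i.i.d. per-point noise and
    the per-test global shift: CoR = 1.96 * sqrt(2) * sqrt(sd_point^2 + sd_global^2).
    """
    sd = np.hypot(config.test_noise_sd, config.test_global_sd)
    return 1.96 * np.sqrt(2.0) * sd


# --- cohort generation -------------------------------------------------------

def _rf_counts(rf: float, catch: int) -> tuple[int, int]:
    total = int(round(rf * catch)) if rf > 0.25 else int(np.floor(rf * catch))
    total = min(total, catch)
    return total // 2, total - total // 2


def generate_cohort(
    config: SyntheticConfig,
    compute_volumes: bool = False,
) -> tuple[list[ExamRecord], pd.DataFrame]:
    """Generate a bilateral triplicate-test cohort.

    Returns the 6 * n_subjects exam records and a Table-1-style cohort frame
    (per subject/eye: age, refraction, acuity, and the reference-test OMS —
    missing where no test is reliable; total volume only when
    ``compute_volumes`` is set).  Deterministic given ``config.seed``.
    """
    grids = {Eye.OD: build_grid(Eye.OD), Eye.OS: build_grid(Eye.OS)}
    profile = reference_profile(config, grids[Eye.OD])  # same per point id for OS
    m = _masks(grids[Eye.OD])
    mean_p = profile[m["nonblind"]].mean()
    off_contrib = config.temporal_offset * m["temporal_central"].sum() / m["nonblind"].sum()
    offset_field = np.where(m["temporal_central"], config.temporal_offset, 0.0)

    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    lo, hi = config.age_range
    # jitter-stratified ages: uniform marginal, stable cohort-level spread
    ages = lo + (np.arange(n) + rng.uniform(size=n)) / n * (hi - lo)
    resid = rng.normal(0.0, config.severity_resid_sd, size=n)
    eye_delta = rng.normal(0.0, config.interocular_noise_sd, size=n)
    sphere = np.clip(rng.normal(-2.2, 3.3, size=n), -10.0, 2.5)
    sphere_os = np.clip(sphere + rng.normal(0.0, 0.25, size=n), -10.0, 2.5)
    bcva_noise = rng.normal(0.0, 0.1, size=(n, 2))
    children = rng.spawn(n)

    forced = {(s, Eye(e), t) for s, e, t in config.unreliable_pattern}
    exams: list[ExamRecord] = []
    cohort_rows: list[dict] = []
    for i in range(n):
        subj_no = i + 1
        subj_id = f"s{subj_no:03d}"
        crng = children[i]
        target_od = float(expected_oms(config, ages[i]) + resid[i])
        for eye_idx, eye in enumerate((Eye.OD, Eye.OS)):
            target = target_od if eye is Eye.OD else target_od + float(eye_delta[i])
            s = max((target - off_contrib) / mean_p, 0.02)
            latent = s * profile + offset_field
            eye_exams: list[ExamRecord] = []
            for test in (1, 2, 3):
                shift = float(crng.normal(0.0, config.test_global_sd))
                noise = crng.normal(0.0, config.test_noise_sd, size=grids[eye].n_points)
                if test == 1:
                    shift -= config.learning_offset_test1
                    noise = noise + crng.normal(
                        0.0, config.learning_extra_sd_test1, size=noise.shape
                    )
                values = np.clip(latent + shift + noise, config.floor, config.ceiling)
                if (subj_no, eye, test) in forced:
                    rf = config.unreliable_rf
                else:
                    rf = 0.25 * float(crng.beta(*config.rf_beta))
                fp, fn = _rf_counts(rf, config.rf_catch_trials)
                exam = ExamRecord(
                    subject_id=subj_id, eye=eye, test_index=test,
                    day_index=1 if test <= 2 else 2,
                    sensitivities=values,
                    false_positives=fp, false_negatives=fn,
                    catch_trials=config.rf_catch_trials,
                )
                eye_exams.append(exam)
            exams.extend(eye_exams)
            ref = select_reference_test(eye_exams)
            oms = None if ref is None else overall_mean_sensitivity(ref, grids[eye])
            v_tot = None
            if compute_volumes and ref is not None:
                from .hill import hill_of_vision

                v_tot = hill_of_vision(ref, grids[eye]).v_tot
            bcva = float(np.clip(0.75 - 0.05 * target + bcva_noise[i, eye_idx], -0.1, 1.2))
            cohort_rows.append(
                {
                    "subject_id": subj_id, "eye": eye.value,
                    "best_vision_sphere_d": float(sphere[i] if eye is Eye.OD else sphere_os[i]),
                    "bcva_logmar": round(bcva, 2),
                    "oms_db": np.nan if oms is None else oms,
                    "v_tot_dbsr": np.nan if v_tot is None else v_tot,
                    "age_years": float(ages[i]),
                }
            )
    return exams, pd.DataFrame(cohort_rows)


# --- fixtures & config serialisation ----------------------------------------

def table1_fixture() -> pd.DataFrame:
    """Packaged per-subject cohort table (acuity, refraction, OMS, Vtot).

    Ten subjects, both eyes; one right eye has no OMS/Vtot because all of its
    tests were unreliable (missing, not zero).
    """
    from .grid import packaged_grid_path  # anchor for the data directory

    path = packaged_grid_path().parent / "table1_cohort.csv"
    rows = read_cohort_table(path)
    from .io import cohort_to_frame

    return cohort_to_frame(rows)


def config_to_yaml(config: SyntheticConfig, path: str | Path) -> None:
    import yaml

    d = dataclasses.asdict(config)
    d["age_range"] = list(d["age_range"])
    d["it_center"] = list(d["it_center"])
    d["rf_beta"] = list(d["rf_beta"])
    d["unreliable_pattern"] = [list(t) for t in d["unreliable_pattern"]]
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def config_from_yaml(path: str | Path) -> SyntheticConfig:
    import yaml

    d = yaml.safe_load(Path(path).read_text())
    d["age_range"] = tuple(d["age_range"])
    d["it_center"] = tuple(d["it_center"])
    d["rf_beta"] = tuple(d["rf_beta"])
    d["unreliable_pattern"] = tuple(tuple(t) for t in d["unreliable_pattern"])
    return SyntheticConfig(**d)
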