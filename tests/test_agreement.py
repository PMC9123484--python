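"""Bland-Altman agreement, floor handling, symmetry gating, derived statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from perifield.agreement import (
    agreement_from_differences,
    bland_altman,
    bonferroni_alpha,
    consecutive_reliable_pairs,
    interocular_symmetry,
    mean_interocular_difference,
    min_detectable_interval,
    pointwise_repeatability,
    select_reference_test,
)
from helpers import make_exam


class TestBlandAltman:
    def test_identical_pairs_have_zero_cor(self):
        res = bland_altman([(5.0, 5.0), (7.0, 7.0), (9.0, 9.0)])
        assert res.cor == 0.0
        assert res.loa_lower == res.loa_upper == 0.0

    def test_hand_computed_example(self):
        res = bland_altman([(0, 2), (0, 0), (0, -2)])
        assert res.mean_diff == pytest.approx(0.0)
        assert res.sd_diff == pytest.approx(2.0)
        assert res.cor == pytest.approx(3.92)
        assert res.loa_lower == pytest.approx(-3.92)
        assert res.loa_upper == pytest.approx(3.92)

    def test_printed_loa_width_recovers_cor(self):
        # half the width of published limits of agreement equals the CoR
        loa_lower, loa_upper, printed_cor = -2.77, 2.06, 2.41
        assert (loa_upper - loa_lower) / 2 == pytest.approx(printed_cor, abs=0.01)

    def test_antisymmetry_under_pair_swap(self):
        rng = np.random.default_rng(8)
        pairs = rng.normal(10, 3, size=(20, 2))
        fwd = bland_altman(pairs)
        rev = bland_altman(pairs[:, ::-1])
        assert rev.mean_diff == pytest.approx(-fwd.mean_diff)
        assert rev.loa_lower == pytest.approx(-fwd.loa_upper)
        assert rev.loa_upper == pytest.approx(-fwd.loa_lower)
        assert rev.cor == pytest.approx(fwd.cor)

    def test_fewer_than_two_pairs_rejected(self):
        with pytest.raises(ValueError):
            bland_altman([(1.0, 2.0)])

    def test_internal_identities_on_randomised_instances(self):
        # 1000 randomised instances of the CoR/LoA identities
        rng = np.random.default_rng(123)
        for _ in range(1000):
            n = rng.integers(2, 40)
            diffs = rng.normal(rng.normal(0, 5), rng.uniform(0.1, 10), size=n)
            r = agreement_from_differences(diffs)
            assert r.loa_lower == pytest.approx(r.mean_diff - 1.96 * r.sd_diff)
            assert r.loa_upper == pytest.approx(r.mean_diff + 1.96 * r.sd_diff)
            assert r.cor == pytest.approx((r.loa_upper - r.loa_lower) / 2)
            assert r.mean_diff == pytest.approx((r.loa_upper + r.loa_lower) / 2)


class TestPointwiseRepeatability:
    def _toy_exams(self):
        a = np.zeros(185)
        b = np.zeros(185)
        a[:4] = [0, 10, 0, 8]
        b[:4] = [5, 12, 0, 8]
        return a, b

    def test_floor_exclusion_hand_example(self):
        a, b = self._toy_exams()
        res = pointwise_repeatability(a[:4], b[:4], floor_exclude=True)
        assert res.n_pairs == 2
        assert res.mean_diff == pytest.approx(1.0)
        assert res.cor == pytest.approx(1.96 * np.sqrt(2), abs=1e-9)

    def test_floor_exclusion_off_keeps_all(self):
        a, b = self._toy_exams()
        res = pointwise_repeatability(a[:4], b[:4], floor_exclude=False)
        assert res.n_pairs == 4

    def test_identical_exams_zero_cor(self, od_grid):
        v = np.linspace(1, 30, 185)
        res = pointwise_repeatability(v, v, grid=od_grid)
        assert res.cor == 0.0
        assert res.n_pairs == 185 - int(od_grid.is_blind_spot.sum())

    def test_blind_spot_points_dropped_with_grid(self, od_grid):
        v = np.full(185, 10.0)
        res = pointwise_repeatability(v, v, grid=od_grid, floor_exclude=False)
        assert res.n_pairs == 183

    def test_mismatched_subject_rejected(self):
        e1 = make_exam(subject="a", values=np.ones(185))
        e2 = make_exam(subject="b", values=np.ones(185))
        with pytest.raises(ValueError, match="same subject"):
            pointwise_repeatability(e1, e2)

    def test_no_surviving_pairs_rejected(self):
        with pytest.raises(ValueError, match="no surviving"):
            pointwise_repeatability(np.zeros(10), np.ones(10), floor_exclude=True)


class TestInterocularSymmetry:
    def test_identical_eyes_r_one(self):
        v = np.array([1.0, 4.0, 2.5, 7.0, 5.5])
        res = interocular_symmetry(v, v)
        assert res.coefficient == pytest.approx(1.0)

    def test_missing_subjects_dropped(self):
        od = np.array([1.0, np.nan, 3.0, 4.0, 5.0, 2.0])
        os_ = np.array([1.1, 2.0, 2.9, 4.2, 5.1, 1.8])
        res = interocular_symmetry(od, os_)
        assert res.n == 5

    def test_skewed_data_gates_to_spearman(self):
        rng = np.random.default_rng(2)
        od = np.concatenate([np.zeros(12), rng.uniform(20, 30, 3)])
        os_ = od + rng.normal(0, 0.1, 15)
        res = interocular_symmetry(od, os_)
        assert res.method == "spearman"
        assert min(res.normality_p_od, res.normality_p_os) < 0.05

    def test_normal_data_uses_pearson(self):
        rng = np.random.default_rng(0)
        od = rng.normal(10, 2, 30)
        res = interocular_symmetry(od, od + rng.normal(0, 0.5, 30))
        assert res.method == "pearson"

    def test_pearson_invariant_under_affine_transforms(self):
        rng = np.random.default_rng(4)
        od = rng.normal(10, 2, 25)
        os_ = od + rng.normal(0, 1, 25)
        base = interocular_symmetry(od, os_)
        scaled = interocular_symmetry(3.0 * od + 7.0, 0.5 * os_ - 2.0)
        assert scaled.coefficient == pytest.approx(base.coefficient)

    def test_spearman_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(5)
        od = np.concatenate([np.zeros(10), rng.uniform(5, 9, 5)])
        os_ = od + rng.normal(0, 0.2, 15)
        base = interocular_symmetry(od, os_)
        assert base.method == "spearman"
        mono = interocular_symmetry(np.exp(od / 5), os_)
        assert mono.coefficient == pytest.approx(base.coefficient)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            interocular_symmetry(np.ones(5), np.arange(5.0))


class TestDerivedStatistics:
    @pytest.mark.parametrize(
        "alpha,m,expected", [(0.05, 4, 0.0125), (0.05, 1, 0.05), (0.05, 5, 0.01)]
    )
    def test_bonferroni(self, alpha, m, expected):
        assert bonferroni_alpha(alpha, m) == pytest.approx(expected)

    def test_bonferroni_rejects_zero_comparisons(self):
        with pytest.raises(ValueError):
            bonferroni_alpha(0.05, 0)

    @pytest.mark.parametrize(
        "cor,decline,expected", [(1.72, 0.69, 2.49), (0.0, 0.69, 0.0), (2.0, 1.0, 2.0)]
    )
    def test_min_detectable_interval(self, cor, decline, expected):
        assert min_detectable_interval(cor, decline) == pytest.approx(expected, abs=0.005)

    def test_min_detectable_interval_rejects_nonpositive_decline(self):
        with pytest.raises(ValueError):
            min_detectable_interval(1.72, 0.0)

    def test_mean_interocular_difference(self):
        mean, sd = mean_interocular_difference([1.0, 5.0], [2.0, 3.0])
        assert mean == pytest.approx(1.5)
        assert sd == pytest.approx(np.std([1.0, 2.0], ddof=1))

    def test_mean_interocular_difference_identical_eyes(self):
        mean, _ = mean_interocular_difference([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert mean == 0.0

    def test_mean_interocular_difference_no_pairs(self):
        with pytest.raises(ValueError):
            mean_interocular_difference([np.nan], [1.0])


class TestTestSelection:
    def _triplicate(self, rfs):
        return [
            make_exam(rf_counts=(int(rf * 20), 0, 20), test=i + 1, values=np.ones(185))
            for i, rf in enumerate(rfs)
        ]

    def test_reference_is_last_reliable(self):
        exams = self._triplicate([0.1, 0.1, 0.4])
        assert select_reference_test(exams).test_index == 2
        exams = self._triplicate([0.1, 0.1, 0.2])
        assert select_reference_test(exams).test_index == 3

    def test_reference_none_when_all_unreliable(self):
        assert select_reference_test(self._triplicate([0.4, 0.5, 0.3])) is None

    def test_consecutive_pairs_skip_unreliable_members(self):
        exams = self._triplicate([0.4, 0.1, 0.1])
        pairs = consecutive_reliable_pairs(exams)
        assert [(a.test_index, b.test_index) for a, b in pairs] == [(2, 3)]


class TestParameterRecovery:
    def test_oms_noise_recovery_on_synthetic_triplicates(self):
        # i.i.d. per-test noise with SD sigma on a per-subject summary measure:
        # the Bland-Altman CoR estimates 1.96 * sqrt(2) * sigma
        rng = np.random.default_rng(42)
        sigma, n = 0.6, 200
        truth = rng.uniform(2, 12, n)
        t1 = truth + rng.normal(0, sigma, n)
        t2 = truth + rng.normal(0, sigma, n)
        res = bland_altman(np.column_stack([t1, t2]))
        assert res.cor == pytest.approx(1.96 * np.sqrt(2) * sigma, rel=0.05)
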