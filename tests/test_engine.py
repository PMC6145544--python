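"""Replication engine: each pipeline step against an independent oracle."""

import numpy as np
import pytest
from scipy import stats

from mcgurksim import (
    CalibrationError,
    CohortParams,
    DegenerateDataError,
    EmptyInputError,
    InvalidDesignError,
    StudyDesign,
    SusceptibilityMatrix,
    apply_shift,
    assign_groups,
    calibrate_shift,
    resample_subjects,
    run_replications,
    run_single_study,
    sample_observed_rates,
)
from mcgurksim import test_group_difference as group_difference_ttest
from conftest import default_flat_params


def matrix(rows):
    return SusceptibilityMatrix(np.asarray(rows, dtype=float))


class TestResample:
    def test_single_subject_source_repeats(self):
        src = matrix([[40.0, 60.0]])
        out = resample_subjects(src, 3, np.random.default_rng(0))
        assert out.values.shape == (3, 2)
        assert np.all(out.values == [40.0, 60.0])

    def test_zero_draws_empty_same_columns(self):
        src = matrix([[1, 2, 3], [4, 5, 6]])
        out = resample_subjects(src, 0, np.random.default_rng(0))
        assert out.values.shape == (0, 3)

    def test_empty_source_rejected(self):
        src = SusceptibilityMatrix(np.empty((0, 2)))
        with pytest.raises(EmptyInputError):
            resample_subjects(src, 5, np.random.default_rng(0))

    def test_rows_stay_intact_and_uniform(self):
        # chi-square goodness of fit of resampled row frequencies vs uniform
        rng = np.random.default_rng(123)
        ids = np.arange(165)
        src = matrix(np.column_stack([ids * 0.5, ids * 0.5 + 1.0]))
        out = resample_subjects(src, 100_000, rng)
        # intactness: column 1 is always column 0 + 1 in the source
        np.testing.assert_array_equal(out.values[:, 1], out.values[:, 0] + 1.0)
        counts = np.bincount(
            np.rint(out.values[:, 0] / 0.5).astype(int), minlength=165
        )
        chi2 = ((counts - 100_000 / 165) ** 2 / (100_000 / 165)).sum()
        assert stats.chi2.sf(chi2, df=164) > 1e-4


class TestAssign:
    def test_balanced(self):
        labels = assign_groups(4, np.random.default_rng(0))
        assert sorted(labels) == ["A", "A", "B", "B"]

    def test_odd_rejected(self):
        with pytest.raises(InvalidDesignError):
            assign_groups(3, np.random.default_rng(0))

    def test_all_balanced_patterns_equally_likely(self):
        # exact enumeration oracle: 6 balanced patterns of AABB, each 1/6
        rng = np.random.default_rng(7)
        counts = {}
        n = 12_000
        for _ in range(n):
            key = "".join(assign_groups(4, rng))
            counts[key] = counts.get(key, 0) + 1
        assert len(counts) == 6
        chi2 = sum((c - n / 6) ** 2 / (n / 6) for c in counts.values())
        assert stats.chi2.sf(chi2, df=5) > 1e-4


class TestShift:
    def test_shift_and_truncation_cases(self):
        src = matrix([[50.0], [90.0], [2.0]])
        labels = np.array(["B", "B", "A"])
        out = apply_shift(src, labels, 10.0, (5, 95))
        assert out.values[0, 0] == 60.0
        out = apply_shift(src, labels, 17.25, (5, 95))
        assert out.values[1, 0] == 95.0  # ceiling truncation
        # truncation applies to group A as well
        assert out.values[2, 0] == 5.0

    def test_group_a_only_clamped(self):
        src = matrix([[50.0, 40.0]])
        out = apply_shift(src, np.array(["A"]), 30.0, (5, 95))
        np.testing.assert_array_equal(out.values, [[50.0, 40.0]])


class TestBinomialSampling:
    def test_t1_gives_all_or_nothing(self):
        src = matrix([[5.0, 50.0, 95.0]])
        out = sample_observed_rates(src, 1, np.random.default_rng(0))
        assert set(np.unique(out.values)) <= {0.0, 100.0}

    def test_exact_binomial_distribution_at_t2(self):
        # pM=50, T=2 -> observed in {0,50,100} with probs {1/4,1/2,1/4}
        src = matrix(np.full((30_000, 1), 50.0))
        out = sample_observed_rates(src, 2, np.random.default_rng(3))
        values, counts = np.unique(out.values, return_counts=True)
        assert list(values) == [0.0, 50.0, 100.0]
        freqs = counts / counts.sum()
        np.testing.assert_allclose(freqs, [0.25, 0.5, 0.25], atol=0.01)

    def test_large_trial_limit_recovers_truth(self):
        src = matrix([[5.0]])
        out = sample_observed_rates(src, 100_000, np.random.default_rng(4))
        assert abs(out.values[0, 0] - 5.0) < 0.5


class TestTTest:
    def test_closed_form_oracle(self):
        # groups {40,50,60} vs {50,60,70}: diff 10, t = 1.2247, p ~ 0.288
        obs = matrix([[40], [50], [60], [50], [60], [70]])
        labels = np.array(["A"] * 3 + ["B"] * 3)
        r = group_difference_ttest(obs, labels, alpha=0.05)
        assert r.diff_estimate == pytest.approx(10.0)
        assert r.t_statistic == pytest.approx(1.224745, abs=1e-5)
        assert r.df == 4
        assert r.p_value == pytest.approx(0.2879, abs=1e-3)
        assert not r.significant

    def test_matches_scipy_ttest_ind(self):
        rng = np.random.default_rng(11)
        vals = rng.uniform(0, 100, size=(20, 3))
        obs = SusceptibilityMatrix(vals)
        labels = np.array(["A"] * 10 + ["B"] * 10)
        r = group_difference_ttest(obs, labels)
        means = vals.mean(axis=1)
        t_ref, p_ref = stats.ttest_ind(means[10:], means[:10], equal_var=True)
        assert r.t_statistic == pytest.approx(t_ref, rel=1e-10)
        assert r.p_value == pytest.approx(p_ref, rel=1e-10)

    def test_antisymmetry_under_group_swap(self):
        obs = matrix([[40], [55], [62], [50], [61], [72]])
        labels = np.array(["A"] * 3 + ["B"] * 3)
        r1 = group_difference_ttest(obs, labels)
        swapped = np.where(labels == "A", "B", "A")
        r2 = group_difference_ttest(obs, swapped)
        assert r2.diff_estimate == pytest.approx(-r1.diff_estimate)
        assert r2.p_value == pytest.approx(r1.p_value)

    def test_zero_variance_degenerate(self):
        obs = matrix([[50], [50], [50], [50]])
        labels = np.array(["A", "A", "B", "B"])
        with pytest.raises(DegenerateDataError):
            group_difference_ttest(obs, labels)


class TestSingleStudyAndReplications:
    def test_determinism(self, default_params):
        src = SusceptibilityMatrix(
            np.random.default_rng(1).uniform(0, 100, (200, 4))
        )
        design = StudyDesign(n_total=20, true_diff=10, shift=12, n_stimuli=4, n_trials=10)
        r1 = run_single_study(design, src, np.random.default_rng(77))
        r2 = run_single_study(design, src, np.random.default_rng(77))
        assert r1 == r2
        reps1 = run_replications(design, src, 50, seed=5)
        reps2 = run_replications(design, src, 50, seed=5)
        np.testing.assert_array_equal(reps1.p_value, reps2.p_value)

    def test_null_rejection_rate_matches_alpha(self):
        # with zero shift the t-test should reject at ~ alpha
        params = default_flat_params()
        design = StudyDesign(n_total=40, true_diff=0, shift=0, n_stimuli=4, n_trials=20)
        reps = run_replications(design, params, 4000, seed=9, source_size=5000)
        power = reps.significant.mean()
        se = np.sqrt(0.05 * 0.95 / 4000)
        assert abs(power - 0.05) < 3 * se + 0.005

    def test_single_replication_and_length(self):
        design = StudyDesign(n_total=10, true_diff=0, shift=0, n_stimuli=2, n_trials=5)
        reps = run_replications(design, default_flat_params(), 1, seed=2, source_size=500)
        assert reps.n_reps == 1
        assert len(list(reps)) == 1

    def test_degenerate_studies_counted_nonsignificant(self):
        # T=1 with tiny N can produce all-identical observed rates
        point = CohortParams(
            mixture_weights=(0.0, 1.0, 0.0),
            component_params=((0, 0), (50.0, 0.0), (100, 0)),
            subject_effect_sd=0, stimulus_effect_sd=0, residual_sd=0,
            target_mean=50, target_sd=1,
        )
        design = StudyDesign(n_total=4, true_diff=0, shift=0, n_stimuli=1, n_trials=1)
        reps = run_replications(design, point, 200, seed=3, source_size=50)
        degenerate = reps.p_value == 1.0
        assert degenerate.any()
        assert not reps.significant[degenerate].any()

    def test_csv_export(self, tmp_path):
        design = StudyDesign(n_total=10, true_diff=0, shift=0, n_stimuli=2, n_trials=5)
        reps = run_replications(design, default_flat_params(), 25, seed=4, source_size=500)
        path = tmp_path / "reps.csv"
        reps.to_csv(path)
        import pandas as pd

        df = pd.read_csv(path)
        assert len(df) == 25
        assert (df["significant"] == (df["p_value"] < 0.05)).all()


class TestShiftCalibration:
    def test_zero_target(self, default_params):
        assert calibrate_shift(0.0, default_params) == 0.0

    def test_degenerate_cohort_no_truncation(self):
        point = SusceptibilityMatrix(np.full((1000, 2), 50.0))
        assert calibrate_shift(10.0, point) == pytest.approx(10.0)

    def test_shift_exceeds_target_when_truncation_binds(self, default_params, shift10):
        assert shift10 > 10.0

    def test_monotone_in_target(self, default_params):
        s5 = calibrate_shift(5.0, default_params, calib_n=10_000, calib_stimuli=50, seed=6)
        s10 = calibrate_shift(10.0, default_params, calib_n=10_000, calib_stimuli=50, seed=6)
        s20 = calibrate_shift(20.0, default_params, calib_n=10_000, calib_stimuli=50, seed=6)
        assert s5 < s10 < s20
        assert s5 > 5.0 and s20 > 20.0

    def test_unreachable_target(self, default_params):
        with pytest.raises(CalibrationError):
            calibrate_shift(95.0, default_params, calib_n=5_000, calib_stimuli=20)


class TestDesignValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_total": 3},
            {"n_total": 2},
            {"alpha": 0.0},
            {"alpha": 1.0},
            {"n_stimuli": 0},
            {"n_trials": 0},
            {"truncation_bounds": (95, 5)},
        ],
    )
    def test_invalid_designs_rejected(self, kwargs):
        base = dict(n_total=30, true_diff=10, shift=12, n_stimuli=4, n_trials=10)
        base.update(kwargs)
        with pytest.raises(InvalidDesignError):
            StudyDesign(**base)
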