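"""Long-run metrics: arithmetic oracles, identities, normal-theory closed forms."""

import numpy as np
import pytest
from scipy import stats

from mcgurksim import (
    EmptyInputError,
    ReplicationSet,
    StudyDesign,
    StudyResult,
    UndefinedMetricError,
    analytic_design_oracle,
    compute_effect_inflation,
    compute_power,
    compute_sign_error,
    summarize_longrun,
)


def make_repset(estimates, p_values, alpha=0.05):
    design = StudyDesign(n_total=30, true_diff=10, shift=12, alpha=alpha)
    results = [
        StudyResult(
            mean_a=45.0, mean_b=45.0 + e, diff_estimate=e,
            t_statistic=0.0, df=28, p_value=p, significant=p < alpha,
        )
        for e, p in zip(estimates, p_values)
    ]
    return ReplicationSet.from_results(design, results)


class TestScalarMetrics:
    def test_power_extremes(self):
        assert compute_power(make_repset([1, 2], [0.01, 0.04])) == 1.0
        assert compute_power(make_repset([1, 2], [0.5, 0.9])) == 0.0

    def test_inflation_arithmetic(self):
        reps = make_repset([20, 40, 5], [0.01, 0.01, 0.5])
        assert compute_effect_inflation(reps, 10.0) == pytest.approx(3.0)

    def test_inflation_uses_absolute_values(self):
        reps = make_repset([-10, 10], [0.01, 0.01])
        assert compute_effect_inflation(reps, 10.0) == pytest.approx(1.0)

    def test_sign_error_fraction(self):
        reps = make_repset([20, -5, 15], [0.01, 0.01, 0.01])
        assert compute_sign_error(reps, 10.0) == pytest.approx(1 / 3)
        reps = make_repset([20, 5, 15], [0.01, 0.01, 0.01])
        assert compute_sign_error(reps, 10.0) == 0.0

    def test_undefined_without_significant_reps(self):
        reps = make_repset([1, 2], [0.5, 0.6])
        with pytest.raises(UndefinedMetricError):
            compute_effect_inflation(reps, 10.0)
        with pytest.raises(UndefinedMetricError):
            compute_sign_error(reps, 10.0)


class TestSummary:
    def test_weighted_recovery_example(self):
        # power 2/3, published mean 13, discarded mean 5 -> recovery ~ 10.3
        reps = make_repset([13, 13, 5], [0.01, 0.01, 0.5])
        s = summarize_longrun(reps, true_diff=10)
        assert s.power == pytest.approx(2 / 3)
        assert s.published_mean == pytest.approx(13.0)
        assert s.discarded_mean == pytest.approx(5.0)
        assert s.weighted_recovery == pytest.approx(13 * 2 / 3 + 5 / 3)

    def test_all_significant_recovery_equals_published(self):
        reps = make_repset([12, 18], [0.01, 0.02])
        s = summarize_longrun(reps, true_diff=10)
        assert s.weighted_recovery == pytest.approx(s.published_mean)
        assert np.isnan(s.discarded_mean)

    def test_decomposition_identity_exact(self):
        rng = np.random.default_rng(5)
        est = rng.normal(10, 15, size=500)
        p = rng.uniform(0, 1, size=500)
        reps = make_repset(est, p)
        s = summarize_longrun(reps, true_diff=10)
        manual = s.power * s.published_mean + (1 - s.power) * s.discarded_mean
        assert manual == pytest.approx(est.mean(), rel=1e-12)
        assert s.weighted_recovery == pytest.approx(est.mean(), rel=1e-12)

    def test_empty_rejected(self):
        design = StudyDesign(n_total=30, true_diff=10, shift=12)
        reps = ReplicationSet.from_results(design, [])
        with pytest.raises(EmptyInputError):
            summarize_longrun(reps, true_diff=10)


class TestAnalyticOracle:
    def test_against_monte_carlo_normal(self):
        # independent route: raw normal draws of the estimated difference
        effect, sd, n = 10.0, 36.7, 150
        se = sd * np.sqrt(2 / n)
        rng = np.random.default_rng(17)
        x = rng.normal(effect, se, size=400_000)
        reject = np.abs(x) > stats.norm.isf(0.025) * se
        mc_power = reject.mean()
        mc_exag = np.abs(x[reject]).mean() / effect
        mc_sign = (x[reject] < 0).mean()
        o = analytic_design_oracle(effect, sd, n)
        assert o["power"] == pytest.approx(mc_power, abs=0.005)
        assert o["exaggeration"] == pytest.approx(mc_exag, abs=0.01)
        assert o["sign_error"] == pytest.approx(mc_sign, abs=0.002)
        assert o["power"] == pytest.approx(0.66, abs=0.01)

    def test_high_power_limit(self):
        o = analytic_design_oracle(effect=10.0, per_subject_sd=1.0, n_per_group=100)
        assert o["power"] == pytest.approx(1.0, abs=1e-6)
        assert o["exaggeration"] == pytest.approx(1.0, abs=1e-6)
        assert o["sign_error"] == pytest.approx(0.0, abs=1e-9)

    def test_vanishing_effect_sign_error_half(self):
        o = analytic_design_oracle(effect=1e-9, per_subject_sd=30.0, n_per_group=20)
        assert o["sign_error"] == pytest.approx(0.5, abs=1e-3)
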