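import numpy as np
import pytest

from mcgurksim import (
    CohortParams,
    calibrate_shift,
    default_cohort_params,
    generate_cohort,
)


@pytest.fixture(scope="session")
def default_params():
    """The calibrated default study population (mean 45, SD 36.7)."""
    return default_cohort_params()


@pytest.fixture(scope="session")
def shift10(default_params):
    """Shift realizing a 10-point mean difference on the default population."""
    return calibrate_shift(10.0, default_params, seed=1234)


@pytest.fixture(scope="session")
def normal_cohort():
    """A near-normal, truncation-inactive population for oracle comparisons.

    Single middle component at 50 with SD 12: essentially no mass near the
    [5, 95] truncation bounds, so shift == realized difference and the
    normal-theory closed forms apply.
    """
    return CohortParams(
        mixture_weights=(0.0, 1.0, 0.0),
        component_params=((5.0, 1.0), (50.0, 12.0), (95.0, 1.0)),
        subject_effect_sd=0.0,
        stimulus_effect_sd=0.0,
        residual_sd=4.0,
        target_mean=50.0,
        target_sd=12.0,
    )


@pytest.fixture
def small_matrix():
    """A tiny fixed susceptibility matrix for step-level unit tests."""
    rng = np.random.default_rng(99)
    return generate_cohort(default_flat_params(), 6, 3, rng)


def default_flat_params() -> CohortParams:
    """Cheap uncalibrated params for structural tests (no moment claims)."""
    return CohortParams(
        mixture_weights=(0.3, 0.4, 0.3),
        component_params=((2.0, 3.0), (45.0, 15.0), (90.0, 4.0)),
        subject_effect_sd=0.0,
        stimulus_effect_sd=8.0,
        residual_sd=6.0,
        target_mean=45.0,
        target_sd=35.0,
    )
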