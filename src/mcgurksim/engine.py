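"""Simulated two-group McGurk studies and their long-run replication.

One simulated experiment proceeds exactly in this order:

1. resample ``N`` subjects (rows) with replacement from a source population,
2. randomly assign them to two equal groups A and B,
3. add a fixed shift to every susceptibility of group B, then truncate all
   susceptibilities (both groups) to [5, 95] so every binomial draw stays
   stochastic,
4. replace each true susceptibility by an observed rate from ``T`` binomial
   trials per stimulus,
5. average observed rates across stimuli within subject and compare groups
   with a two-sample pooled-variance t-test (two-sided).

Because of ceiling effects on the bounded percent scale, the shift applied to
group B must exceed the desired mean population difference;
:func:`calibrate_shift` finds the shift whose realized (post-truncation) mean
difference equals the target.

Repeating step 1-5 many times (:func:`run_replications`) gives the long-run
distribution of study outcomes from which power, effect inflation and sign
errors are computed (see :mod:`mcgurksim.metrics`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from ._errors import (
    CalibrationError,
    DegenerateDataError,
    EmptyInputError,
    InvalidDesignError,
)
from .cohort import CohortParams, SusceptibilityMatrix, generate_cohort

__all__ = [
    "StudyDesign",
    "StudyResult",
    "ReplicationSet",
    "resample_subjects",
    "assign_groups",
    "apply_shift",
    "sample_observed_rates",
    "test_group_difference",
    "run_single_study",
    "run_replications",
    "calibrate_shift",
    "realized_difference",
    "DEFAULT_BOUNDS",
    "DEFAULT_N_REPS",
    "DEFAULT_SOURCE_SIZE",
]

DEFAULT_BOUNDS = (5.0, 95.0)
#: Long-run replication count used for headline results.
DEFAULT_N_REPS = 35_000
#: Size of the synthetic source population a cohort is realized at before
#: bootstrap resampling, when the caller passes CohortParams rather than a
#: fixed matrix. Large enough that resampling is effectively fresh draws.
DEFAULT_SOURCE_SIZE = 20_000


@dataclass(frozen=True)
class StudyDesign:
    """Parameters of one simulated two-group experiment.

    ``true_diff`` is the intended mean population difference E (percent,
    B minus A); ``shift`` is the raw shift added to group B before
    truncation, normally obtained from :func:`calibrate_shift` so the
    realized difference equals ``true_diff``.
    """

    n_total: int
    true_diff: float
    shift: float
    n_stimuli: int = 8
    n_trials: int = 100
    alpha: float = 0.05
    truncation_bounds: tuple[float, float] = DEFAULT_BOUNDS

    def __post_init__(self) -> None:
        if self.n_total < 4 or self.n_total % 2:
            raise InvalidDesignError(
                f"n_total must be even and >= 4, got {self.n_total}"
            )
        if not (0 < self.alpha < 1):
            raise InvalidDesignError("alpha must lie in (0, 1)")
        if self.n_stimuli < 1 or self.n_trials < 1:
            raise InvalidDesignError("n_stimuli and n_trials must be >= 1")
        low, high = self.truncation_bounds
        if not (0 <= low < high <= 100):
            raise InvalidDesignError("truncation bounds must satisfy 0 <= low < high <= 100")

    def to_dict(self) -> dict:
        return {
            "n_total": self.n_total,
            "true_diff": self.true_diff,
            "shift": self.shift,
            "n_stimuli": self.n_stimuli,
            "n_trials": self.n_trials,
            "alpha": self.alpha,
            "truncation_bounds": list(self.truncation_bounds),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StudyDesign":
        d = dict(d)
        if "truncation_bounds" in d:
            d["truncation_bounds"] = tuple(d["truncation_bounds"])
        return cls(**d)


@dataclass(frozen=True)
class StudyResult:
    """Outcome of one simulated experiment (percent scale, B minus A)."""

    mean_a: float
    mean_b: float
    diff_estimate: float
    t_statistic: float
    df: int
    p_value: float
    significant: bool


class ReplicationSet:
    """The long-run collection of :class:`StudyResult` for one design.

    Stores results column-wise in numpy arrays for fast summarization but
    iterates as :class:`StudyResult` records.
    """

    _FIELDS = ("mean_a", "mean_b", "diff_estimate", "t_statistic", "df", "p_value")

    def __init__(self, design: StudyDesign, table: dict[str, np.ndarray], seed: int):
        self.design = design
        self.seed = seed
        for name in self._FIELDS:
            setattr(self, name, np.asarray(table[name]))
        self.significant = self.p_value < design.alpha
        n = len(self.p_value)
        if any(len(getattr(self, f)) != n for f in self._FIELDS):
            raise ValueError("result columns must have equal length")

    @property
    def n_reps(self) -> int:
        return len(self.p_value)

    def __len__(self) -> int:
        return self.n_reps

    def __getitem__(self, i: int) -> StudyResult:
        return StudyResult(
            mean_a=float(self.mean_a[i]),
            mean_b=float(self.mean_b[i]),
            diff_estimate=float(self.diff_estimate[i]),
            t_statistic=float(self.t_statistic[i]),
            df=int(self.df[i]),
            p_value=float(self.p_value[i]),
            significant=bool(self.significant[i]),
        )

    def __iter__(self) -> Iterator[StudyResult]:
        return (self[i] for i in range(self.n_reps))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {f: getattr(self, f) for f in self._FIELDS} | {"significant": self.significant}
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_results(
        cls, design: StudyDesign, results: Sequence[StudyResult], seed: int = 0
    ) -> "ReplicationSet":
        table = {
            f: np.array([getattr(r, f) for r in results]) for f in cls._FIELDS
        }
        return cls(design, table, seed)


# -- single-study steps ----------------------------------------------------


def resample_subjects(
    source: SusceptibilityMatrix, n: int, rng: np.random.Generator
) -> SusceptibilityMatrix:
    """Bootstrap ``n`` subject rows with replacement; rows stay intact."""
    if source.n_subjects < 1:
        raise EmptyInputError("cannot resample from an empty source population")
    idx = rng.integers(0, source.n_subjects, size=n)
    return SusceptibilityMatrix(
        source.values[idx], subject_ids=[source.subject_ids[i] for i in idx]
    )


def assign_groups(n_total: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform random balanced assignment: n/2 labels 'A' and n/2 labels 'B'."""
    if n_total % 2:
        raise InvalidDesignError(f"n_total must be even, got {n_total}")
    labels = np.array(["A", "B"]).repeat(n_total // 2)
    return rng.permutation(labels)


def apply_shift(
    matrix: SusceptibilityMatrix,
    labels: np.ndarray,
    shift: float,
    bounds: tuple[float, float] = DEFAULT_BOUNDS,
) -> SusceptibilityMatrix:
    """Shift group-B rows by ``shift``, then truncate *all* rows to ``bounds``."""
    low, high = bounds
    if not low < high:
        raise InvalidDesignError("bounds must satisfy low < high")
    values = matrix.values.copy()
    is_b = np.asarray(labels) == "B"
    values[is_b] += shift
    values = np.clip(values, low, high)
    return SusceptibilityMatrix(values, subject_ids=matrix.subject_ids)


def sample_observed_rates(
    matrix: SusceptibilityMatrix, n_trials: int, rng: np.random.Generator
) -> SusceptibilityMatrix:
    """Replace each true rate by an observed rate from ``n_trials`` binomial trials."""
    if n_trials < 1:
        raise InvalidDesignError("n_trials must be >= 1")
    counts = rng.binomial(n_trials, matrix.values / 100.0)
    return SusceptibilityMatrix(
        100.0 * counts / n_trials, subject_ids=matrix.subject_ids
    )


def test_group_difference(
    observed: SusceptibilityMatrix, labels: np.ndarray, alpha: float = 0.05
) -> StudyResult:
    """Two-sample pooled-variance t-test on per-subject mean observed rates.

    Rates are first averaged across stimuli within subject; the test then
    compares the two groups of per-subject means (df = n_total - 2,
    two-sided). Zero pooled variance raises :class:`DegenerateDataError`.
    """
    labels = np.asarray(labels)
    means = observed.subject_means()
    a = means[labels == "A"]
    b = means[labels == "B"]
    if len(a) < 2 or len(b) < 2:
        raise InvalidDesignError("each group needs at least two subjects")
    df = len(a) + len(b) - 2
    pooled_var = ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1)) / df
    diff = b.mean() - a.mean()
    if pooled_var <= 0:
        raise DegenerateDataError("zero pooled variance: t statistic undefined")
    se = np.sqrt(pooled_var * (1.0 / len(a) + 1.0 / len(b)))
    t = diff / se
    p = 2.0 * stats.t.sf(abs(t), df)
    return StudyResult(
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        diff_estimate=float(diff),
        t_statistic=float(t),
        df=int(df),
        p_value=float(p),
        significant=bool(p < alpha),
    )


def run_single_study(
    design: StudyDesign,
    source: SusceptibilityMatrix,
    rng: np.random.Generator,
) -> StudyResult:
    """Execute resample -> assign -> shift/truncate -> binomial -> t-test."""
    if source.n_stimuli != design.n_stimuli:
        raise InvalidDesignError(
            f"source has {source.n_stimuli} stimuli but design wants {design.n_stimuli}"
        )
    sample = resample_subjects(source, design.n_total, rng)
    labels = assign_groups(design.n_total, rng)
    shifted = apply_shift(sample, labels, design.shift, design.truncation_bounds)
    observed = sample_observed_rates(shifted, design.n_trials, rng)
    return test_group_difference(observed, labels, design.alpha)


def _as_source(
    source: SusceptibilityMatrix | CohortParams,
    n_stimuli: int,
    seed_seq: np.random.SeedSequence,
    source_size: int,
) -> SusceptibilityMatrix:
    if isinstance(source, CohortParams):
        child = np.random.default_rng(seed_seq.spawn(1)[0])
        return generate_cohort(source, source_size, n_stimuli, child)
    return source


def run_replications(
    design: StudyDesign,
    source: SusceptibilityMatrix | CohortParams,
    n_reps: int,
    seed: int,
    *,
    source_size: int = DEFAULT_SOURCE_SIZE,
) -> ReplicationSet:
    """Run ``n_reps`` independent simulated studies of one design.

    A master seed spawns one substream per replication, so results for the
    first k replications do not depend on ``n_reps``. If ``source`` is
    :class:`CohortParams`, a synthetic source population of ``source_size``
    subjects is realized first and bootstrapped thereafter. Studies with zero
    pooled variance (possible at T=1 or tiny N) are recorded as
    non-significant with p = 1: a study with no variance cannot reject.
    """
    if n_reps < 1:
        raise EmptyInputError("n_reps must be >= 1")
    master = np.random.SeedSequence(seed)
    src_seq, rep_seq = master.spawn(2)
    src = _as_source(source, design.n_stimuli, src_seq, source_size)
    if src.n_subjects < 1:
        raise EmptyInputError("source population is empty")

    cols = {f: np.empty(n_reps) for f in ReplicationSet._FIELDS}
    df_val = design.n_total - 2
    for i, child in enumerate(rep_seq.spawn(n_reps)):
        rng = np.random.default_rng(child)
        try:
            r = run_single_study(design, src, rng)
        except DegenerateDataError:
            r = StudyResult(
                mean_a=np.nan, mean_b=np.nan, diff_estimate=0.0,
                t_statistic=0.0, df=df_val, p_value=1.0, significant=False,
            )
        cols["mean_a"][i] = r.mean_a
        cols["mean_b"][i] = r.mean_b
        cols["diff_estimate"][i] = r.diff_estimate
        cols["t_statistic"][i] = r.t_statistic
        cols["df"][i] = r.df
        cols["p_value"][i] = r.p_value
    return ReplicationSet(design, cols, seed)


# -- shift calibration -----------------------------------------------------


def realized_difference(
    population: SusceptibilityMatrix,
    shift: float,
    bounds: tuple[float, float] = DEFAULT_BOUNDS,
) -> float:
    """Mean population difference produced by ``shift`` after truncation."""
    low, high = bounds
    vals = population.values
    return float(
        np.clip(vals + shift, low, high).mean() - np.clip(vals, low, high).mean()
    )


def calibrate_shift(
    target_diff: float,
    cohort: CohortParams | SusceptibilityMatrix,
    *,
    calib_n: int = 35_000,
    calib_stimuli: int = 200,
    seed: int = 0,
    bounds: tuple[float, float] = DEFAULT_BOUNDS,
    tol: float = 0.05,
) -> float:
    """Find the group-B shift whose realized mean difference is ``target_diff``.

    Ceiling effects make the realized difference smaller than the raw shift,
    so the returned shift is >= the target whenever truncation binds. The
    realized difference is evaluated on one large simulated population
    (``calib_n`` subjects at ``calib_stimuli`` stimuli) and the shift found by
    monotone root bracketing, to within 0.25 percentage points (default
    tolerance 0.05).
    """
    low, high = bounds
    width = high - low
    if target_diff == 0:
        return 0.0
    if not (0 < abs(target_diff) < width):
        raise CalibrationError(
            f"target difference {target_diff} unreachable within bounds {bounds}"
        )
    if isinstance(cohort, CohortParams):
        pop = generate_cohort(cohort, calib_n, calib_stimuli, seed)
    else:
        pop = cohort

    sign = 1.0 if target_diff > 0 else -1.0
    mag = abs(target_diff)

    def f(s: float) -> float:
        return sign * realized_difference(pop, sign * s, bounds) - mag

    hi = mag
    if f(hi) >= 0:  # truncation inactive at the target: shift == target
        return sign * mag
    # expand the bracket; the realized difference is monotone in the shift
    while f(hi) < 0:
        hi *= 1.6
        if hi > 4 * width:
            raise CalibrationError(
                f"target difference {target_diff} unreachable: even shift {hi:.0f} "
                "cannot produce it after truncation"
            )
    s = optimize.brentq(f, mag, hi, xtol=tol)
    if abs(f(s)) > 0.25:
        raise CalibrationError("shift calibration did not reach 0.25-point accuracy")
    return float(sign * s)
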