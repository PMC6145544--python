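"""Design sweeps over (N, E, S, T) and inversion of the power curve.

Sweeping sample size, true difference, stimulus count and trial count maps
out how statistical power and significance-filtered effect inflation trade
off against data-collection effort; inverting the simulated power curve in N
answers the planning question "how many subjects for 80% power?".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._errors import EmptyInputError, McGurkSimError
from .cohort import CohortParams, SusceptibilityMatrix
from .engine import DEFAULT_SOURCE_SIZE, StudyDesign, calibrate_shift, run_replications
from .metrics import summarize_longrun

__all__ = ["sweep_designs", "find_n_for_power", "PowerSolution", "OutOfRangeError"]


class OutOfRangeError(McGurkSimError, ValueError):
    """The requested power crossing lies outside the simulated N grid.

    ``direction`` is "above" when even the largest N falls short of the
    target and "below" when the smallest N already exceeds it.
    """

    def __init__(self, message: str, direction: str):
        super().__init__(message)
        self.direction = direction


def _seed_for(seed: int, *key) -> int:
    # stable per-cell substream keyed on the cell's values (not its grid
    # position), so results do not depend on grid order
    import zlib

    digest = zlib.crc32(repr(key).encode())
    return int(
        np.random.SeedSequence([seed, digest]).generate_state(1)[0] % (2**31)
    )


def sweep_designs(
    grid: dict[str, list],
    cohort: CohortParams | SusceptibilityMatrix,
    n_reps: int,
    seed: int,
    *,
    alpha: float = 0.05,
    source_size: int = DEFAULT_SOURCE_SIZE,
    shifts: dict[float, float] | None = None,
) -> pd.DataFrame:
    """Full-factorial sweep; one tidy row per (N, E, S, T) cell.

    ``grid`` maps ``n_total``, ``true_diff``, ``n_stimuli``, ``n_trials`` to
    value lists (missing keys get one default). Shifts are calibrated once
    per true difference unless supplied in ``shifts``. Each cell runs on its
    own deterministic substream derived from ``seed`` and the cell
    coordinates, so results do not depend on grid order.
    """
    defaults = {"n_total": [30], "true_diff": [10.0], "n_stimuli": [8], "n_trials": [100]}
    unknown = set(grid) - set(defaults)
    if unknown:
        raise McGurkSimError(f"unknown grid keys: {sorted(unknown)}")
    full = {k: list(grid.get(k, v)) for k, v in defaults.items()}
    if any(len(v) == 0 for v in full.values()):
        raise EmptyInputError("every grid dimension needs at least one value")

    shifts = dict(shifts or {})
    for e in full["true_diff"]:
        if e not in shifts:
            shifts[e] = (
                0.0 if e == 0 else calibrate_shift(e, cohort, seed=_seed_for(seed, 0))
            )

    rows = []
    for n in full["n_total"]:
        for e in full["true_diff"]:
            for s in full["n_stimuli"]:
                for t in full["n_trials"]:
                    design = StudyDesign(
                        n_total=int(n), true_diff=float(e), shift=shifts[e],
                        n_stimuli=int(s), n_trials=int(t), alpha=alpha,
                    )
                    cell_seed = _seed_for(seed, 1, int(n), float(e), int(s), int(t))
                    reps = run_replications(
                        design, cohort, n_reps, cell_seed, source_size=source_size
                    )
                    summary = summarize_longrun(reps)
                    rows.append(design.to_dict() | summary.to_dict())
    df = pd.DataFrame(rows)
    return df.drop(columns=["truncation_bounds"])


@dataclass(frozen=True)
class PowerSolution:
    """Result of inverting a simulated power curve in N."""

    required_n: float
    target_power: float
    grid_n: tuple[int, ...]
    grid_power: tuple[float, ...]
    degenerate: bool  # target met already at the smallest grid N


def find_n_for_power(
    target_power: float,
    design_template: dict,
    cohort: CohortParams | SusceptibilityMatrix,
    n_grid: list[int],
    n_reps: int = 5_000,
    seed: int = 0,
    *,
    source_size: int = DEFAULT_SOURCE_SIZE,
    shift: float | None = None,
) -> PowerSolution:
    """Smallest total N whose interpolated simulated power reaches the target.

    Power is simulated at each N in ``n_grid``, made non-decreasing by a
    running maximum (Monte-Carlo noise can locally invert an intrinsically
    monotone curve), and inverted by piecewise-linear interpolation.

    ``design_template`` supplies ``true_diff`` and optionally ``n_stimuli``,
    ``n_trials``, ``alpha``. Raises :class:`OutOfRangeError` if the crossing
    lies outside the grid.
    """
    if not (0 < target_power < 1):
        raise McGurkSimError("target_power must be in (0, 1)")
    if len(n_grid) < 1:
        raise EmptyInputError("n_grid must be nonempty")
    n_grid = sorted(int(n) for n in n_grid)
    tmpl = dict(design_template)
    e = float(tmpl.pop("true_diff"))
    if shift is None:
        shift = 0.0 if e == 0 else calibrate_shift(e, cohort, seed=_seed_for(seed, 0))

    powers = []
    for n in n_grid:
        design = StudyDesign(n_total=n, true_diff=e, shift=shift, **tmpl)
        reps = run_replications(
            design, cohort, n_reps, _seed_for(seed, 2, n), source_size=source_size
        )
        powers.append(float(reps.significant.mean()))
    mono = np.maximum.accumulate(powers)

    if mono[0] >= target_power:
        return PowerSolution(
            required_n=float(n_grid[0]), target_power=target_power,
            grid_n=tuple(n_grid), grid_power=tuple(powers), degenerate=True,
        )
    if mono[-1] < target_power:
        raise OutOfRangeError(
            f"power reaches only {mono[-1]:.3f} at N={n_grid[-1]}; "
            "extend the grid upward", direction="above",
        )
    j = int(np.searchsorted(mono, target_power))
    n_lo, n_hi = n_grid[j - 1], n_grid[j]
    p_lo, p_hi = mono[j - 1], mono[j]
    frac = 0.0 if p_hi == p_lo else (target_power - p_lo) / (p_hi - p_lo)
    return PowerSolution(
        required_n=float(n_lo + frac * (n_hi - n_lo)),
        target_power=target_power,
        grid_n=tuple(n_grid),
        grid_power=tuple(powers),
        degenerate=False,
    )
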