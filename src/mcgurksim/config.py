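"""Run configuration: one YAML file that reproduces a whole run.

A config fully determines a run together with the master seed; saving the
config and seed next to the outputs is enough to re-run to identical files.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

from ._errors import McGurkSimError
from .cohort import (
    DEFAULT_TARGET_MEAN,
    DEFAULT_TARGET_SD,
    CohortParams,
    calibrate_cohort_params,
)

__all__ = ["RunConfig", "load_config", "save_config"]


@dataclass
class RunConfig:
    """Everything needed to reproduce a simulation run."""

    cohort: CohortParams | None = None  # None -> calibrate to the targets below
    target_mean: float = DEFAULT_TARGET_MEAN
    target_sd: float = DEFAULT_TARGET_SD
    grid: dict = field(default_factory=dict)  # n_total / true_diff / n_stimuli / n_trials lists
    n_reps: int = 5_000
    seed: int = 0
    alpha: float = 0.05
    out_dir: str = "."

    def resolve_cohort(self) -> CohortParams:
        if self.cohort is None:
            self.cohort = calibrate_cohort_params(self.target_mean, self.target_sd)
        return self.cohort

    def to_dict(self) -> dict:
        return {
            "cohort": None if self.cohort is None else self.cohort.to_dict(),
            "target_mean": self.target_mean,
            "target_sd": self.target_sd,
            "grid": self.grid,
            "n_reps": self.n_reps,
            "seed": self.seed,
            "alpha": self.alpha,
            "out_dir": self.out_dir,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        unknown = set(d) - {
            "cohort", "target_mean", "target_sd", "grid",
            "n_reps", "seed", "alpha", "out_dir",
        }
        if unknown:
            raise McGurkSimError(f"unknown config keys: {sorted(unknown)}")
        if d.get("cohort") is not None:
            d["cohort"] = CohortParams.from_dict(d["cohort"])
        return cls(**d)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig.from_dict(data)


def save_config(config: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
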