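"""Exception hierarchy.

All package errors derive from :class:`McGurkSimError` so callers can catch
one base class at pipeline boundaries (the CLI maps them to exit code 1).
"""


class McGurkSimError(Exception):
    """Base class for all mcgurksim errors."""


class ParameterError(McGurkSimError, ValueError):
    """Invalid cohort or model parameters (e.g. mixture weights not summing to 1)."""


class InvalidDesignError(McGurkSimError, ValueError):
    """A study design that cannot be run (odd N, zero stimuli, bad alpha...)."""


class EmptyInputError(McGurkSimError, ValueError):
    """An operation that needs at least one element received none."""


class DegenerateDataError(McGurkSimError, ValueError):
    """Data with zero pooled variance: the t statistic is undefined."""


class CalibrationError(McGurkSimError, RuntimeError):
    """A calibration target that cannot be reached (infeasible moments or shift)."""


class UndefinedMetricError(McGurkSimError, ValueError):
    """A metric conditioned on significance when no replication was significant."""


class TableFormatError(McGurkSimError, ValueError):
    """A comparison table that is malformed (missing columns, bad cells)."""
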