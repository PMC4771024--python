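"""Exception hierarchy shared across the pipeline.

Validation errors signal bad inputs or configuration; numerical errors
signal a computation that could not be completed (non-convergence,
infeasible sampling constraints, degenerate designs).
"""


class SeqmorphError(Exception):
    """Base class for all package errors."""


class ValidationError(SeqmorphError, ValueError):
    """Invalid input data, parameters, or configuration."""


class NumericalError(SeqmorphError, RuntimeError):
    """A numerical procedure failed (non-convergence, infeasibility)."""


class SeparationError(NumericalError):
    """Complete or quasi-complete separation in a regression fit."""
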