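"""Exception hierarchy.

All nestsim errors derive from :class:`NestSimError` (a ``ValueError``), so
callers can catch one type at an API boundary (the CLI maps it to exit code 2).
"""


class NestSimError(ValueError):
    """Base class for all nestsim errors."""


class InvalidParameterError(NestSimError):
    """A model parameter is outside its admissible range."""


class InvalidStateError(NestSimError):
    """A stock value is outside its admissible range (e.g. negative)."""


class InvalidEventError(NestSimError):
    """A disturbance event is malformed (e.g. cut fraction outside [0, 1])."""


class InvalidPlanError(NestSimError):
    """A rotation plan is inconsistent (e.g. rotation age not divisible by the
    cut interval in cohort-pulse mode)."""


class InvalidConfigError(NestSimError):
    """A scenario configuration is invalid (e.g. empty time window)."""


class InvalidInputError(NestSimError):
    """Inputs to a metric or comparison are unusable (e.g. misaligned year
    grids, insufficient overlap)."""


class UndefinedGapError(InvalidInputError):
    """The capacity gap is undefined because mean capacity is zero."""


class NumericalInstabilityError(NestSimError):
    """The integrator produced a non-finite value or a negative overshoot
    beyond the clamping tolerance; reduce the time step ``dt``."""
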