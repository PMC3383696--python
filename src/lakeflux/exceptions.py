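"""Exception types shared across lakeflux modules."""


class DomainError(ValueError):
    """An input is outside the physically meaningful domain of an operation."""


class UndefinedBudgetError(DomainError):
    """A mass budget is undefined (e.g. loss rate and flushing both zero)."""


class InconsistentHydrologyError(DomainError):
    """Redundant hydraulic inputs disagree beyond tolerance."""


class UnidentifiableError(ValueError):
    """A mixing or fitting problem has no identifiable solution."""


class CalibrationError(RuntimeError):
    """A synthetic generator failed its distributional calibration checks."""
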