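"""Exception hierarchy for the event-based model package."""


class EBMError(Exception):
    """Base class for all package errors."""


class SchemaError(EBMError):
    """Input table or schema does not match the declared column roles."""


class DataValidationError(EBMError):
    """A dataset violates an invariant (missing values, bad labels, duplicates)."""


class FitError(EBMError):
    """Mixture fitting failed (degenerate input or infeasible constraint)."""


class NumericalError(EBMError):
    """A numerical routine could not produce a valid result."""


class PairingError(EBMError):
    """Longitudinal visits could not be matched across subjects."""


class MetricError(EBMError):
    """A classification metric is undefined for the given inputs."""
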