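"""Exception types shared across the package."""


class MomentFitError(Exception):
    """Base class for all package errors."""


class ValidationError(MomentFitError, ValueError):
    """Malformed network spec, configuration or input data."""


class NotApplicableError(MomentFitError, ValueError):
    """A moment system was requested for a network outside its validity class."""


class SolverError(MomentFitError, RuntimeError):
    """ODE integration failed; carries the parameter vector for diagnostics."""

    def __init__(self, message, params=None):
        if params is not None:
            message = f"{message} (parameters: {list(params)})"
        super().__init__(message)
        self.params = None if params is None else list(params)


class CostEvaluationError(MomentFitError, RuntimeError):
    """Cost / likelihood evaluation failed at a parameter point."""


class InsufficientReplicatesError(MomentFitError, ValueError):
    """Too few replicates for the requested sample-moment order."""
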