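"""Exception hierarchy shared by all stages."""


class KmclearnError(Exception):
    """Base class for all package errors."""


class InvalidInputError(KmclearnError, ValueError):
    """Malformed domain object (empty molecule, negative counts, ...)."""


class ParameterError(KmclearnError, ValueError):
    """A tunable parameter is outside its admissible range."""


class ConfigurationError(KmclearnError):
    """Missing or inconsistent configuration (e.g. a bond cutoff)."""


class FormatError(KmclearnError):
    """A file or stream does not conform to its declared format."""


class InconsistencyError(KmclearnError):
    """Observed data contradicts the model (e.g. counts for an impossible reaction)."""


class ConvergenceError(KmclearnError):
    """An iterative solver failed to converge; carries iterate diagnostics."""

    def __init__(self, message, *, iterations=None, residual=None, objective=None):
        super().__init__(message)
        self.iterations = iterations
        self.residual = residual
        self.objective = objective


class CapabilityError(KmclearnError):
    """The requested exact computation exceeds what this implementation solves."""


class GeneratorError(KmclearnError):
    """A synthetic-data generator cannot satisfy its guarantees with the given parameters."""
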