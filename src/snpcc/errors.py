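"""Exception hierarchy shared across the package.

``ValidationError`` maps to CLI exit code 2 (bad inputs), ``ComputationError``
to exit code 1 (the inputs were well-formed but the statistic is undefined or
the fit failed).
"""


class SnpccError(Exception):
    """Base class for all package errors."""


class ValidationError(SnpccError, ValueError):
    """Malformed or inconsistent user input."""


class ComputationError(SnpccError, RuntimeError):
    """A statistic or model fit could not be produced from valid inputs."""


class ZeroCellError(ComputationError):
    """A 2x2 cell is zero so the Woolf log-OR machinery is undefined."""


class SeparationError(ComputationError):
    """Perfect separation: a predictor fully determines the outcome."""


class CollinearityError(ComputationError):
    """The design matrix is rank deficient."""
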