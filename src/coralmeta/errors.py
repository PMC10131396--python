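"""Exception hierarchy shared across the pipeline.

Exit-code mapping used by the CLI: ConfigError -> 2, DataError -> 3,
NumericalError -> 4.
"""


class CoralMetaError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(CoralMetaError):
    """Invalid configuration or parameter values."""


class DataError(CoralMetaError):
    """Malformed, inconsistent, or missing input data."""


class DesignError(DataError):
    """Sample design that cannot support the requested analysis."""


class SpecificationError(DataError):
    """A simulation spec references entities that do not exist."""


class NumericalError(CoralMetaError):
    """Numerical failure (non-convergence, stiffness, singularity)."""


class ConvergenceError(NumericalError):
    """Iterative fit failed to converge; carries iteration diagnostics."""

    def __init__(self, message, n_iter=None, last_change=None):
        super().__init__(message)
        self.n_iter = n_iter
        self.last_change = last_change
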