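"""Exception hierarchy shared across the pipeline.

The CLI maps these onto exit codes: ConfigError -> 2, DataError -> 3,
ConvergenceError -> 4.
"""


class CleanFleetError(Exception):
    """Base class for all package errors."""


class ConfigError(CleanFleetError):
    """Invalid configuration value or missing required setting."""


class DataError(CleanFleetError):
    """Malformed, missing, or inconsistent input data."""


class ConvergenceError(CleanFleetError):
    """A model fit failed to converge; carries the bracketing trace."""

    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = trace if trace is not None else []
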