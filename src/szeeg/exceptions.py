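"""Exception hierarchy shared across the package."""


class SzeegError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(SzeegError, ValueError):
    """An argument violates a precondition (bad sizes, ranges, unknown names)."""


class DegenerateInputError(SzeegError, ValueError):
    """The input signal is degenerate for the requested statistic (e.g. constant)."""


class OptimizationError(SzeegError, RuntimeError):
    """An optimizer encountered a non-finite fitness or an internal failure."""


class ConfigError(SzeegError, ValueError):
    """A configuration file or mapping failed validation."""
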