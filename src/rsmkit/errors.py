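"""Exception hierarchy shared across the package."""


class RsmkitError(Exception):
    """Base class for all rsmkit errors."""


class FormatError(RsmkitError, ValueError):
    """A delimited input file violates the expected layout or value range."""


class ConfigurationError(RsmkitError, ValueError):
    """A scale definition, simulation config or pipeline config is invalid."""


class DegenerateDataError(RsmkitError, ValueError):
    """The data cannot support the requested analysis (e.g. everyone excluded)."""


class ConvergenceError(RsmkitError, RuntimeError):
    """Raised only when a non-converged fit is explicitly rejected."""
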