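"""Exception types shared across the package."""


class StratcoxError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(StratcoxError, ValueError):
    """A parameter or specification violates its documented constraints."""


class ConfigError(StratcoxError, ValueError):
    """A configuration file or mapping is malformed (unknown/missing keys)."""


class ConvergenceError(StratcoxError, RuntimeError):
    """The Newton-Raphson fitter failed to converge.

    Carries the iteration trace (list of (iteration, log-likelihood,
    coefficient vector) tuples) for diagnosis, e.g. monotone likelihood.
    """

    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = list(trace) if trace is not None else []
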