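"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """Raised when a config value or curve specification is invalid."""


class ConvergenceError(RuntimeError):
    """Raised when a model fit fails to converge and no usable result exists."""
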