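"""Exception types shared across the package."""


class ConfigError(ValueError):
    """Raised when a simulation or pipeline configuration is inconsistent."""


class InputError(ValueError):
    """Raised when user-supplied data violates an operation's contract."""


class ConvergenceError(RuntimeError):
    """Raised when an iterative procedure fails to reach a stable state."""
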