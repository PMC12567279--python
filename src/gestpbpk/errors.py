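"""Exception hierarchy shared across the package."""


class GestPBPKError(Exception):
    """Base class for all package errors."""


class DomainError(GestPBPKError, ValueError):
    """An argument is outside its physical/mathematical domain."""


class ConfigError(GestPBPKError, ValueError):
    """A configuration, fixture or override is malformed."""


class UsageError(GestPBPKError, ValueError):
    """An operation was called on inputs it cannot meaningfully process."""


class NumericalError(GestPBPKError, RuntimeError):
    """The numerical solver failed; carries diagnostics in args."""


class EstimationError(GestPBPKError, RuntimeError):
    """All optimization restarts failed to converge."""
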