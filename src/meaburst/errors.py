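"""Exception hierarchy shared across the package."""


class MeaburstError(Exception):
    """Base class for all package-specific errors."""


class ElectrodeIDError(MeaburstError, ValueError):
    """Raised for malformed or out-of-grid electrode tokens."""


class FormatError(MeaburstError, ValueError):
    """Raised when a CSV source does not match the expected dialect."""


class ValidationError(MeaburstError, ValueError):
    """Raised when data violates a structural invariant."""


class ConfigError(MeaburstError, ValueError):
    """Raised for inconsistent generator or analysis parameters."""


class DegenerateMatrixError(MeaburstError, ArithmeticError):
    """Raised when an ICC is undefined (e.g. all ratings identical)."""
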