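"""Exception types shared across the package."""


class ConnectocamError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(ConnectocamError, ValueError):
    """Structural or numerical invariant of an input object is violated."""


class DomainError(ConnectocamError, ValueError):
    """A scalar argument lies outside its mathematically valid domain."""


class DegenerateInputError(ConnectocamError, ValueError):
    """The operation is undefined for this input (e.g. all-zero matrix)."""


class ConfigurationError(ConnectocamError, ValueError):
    """A configuration object or file is inconsistent or references unknown entities."""


class DataError(ConnectocamError, ValueError):
    """A dataset is empty, single-class, or otherwise unusable for the requested analysis."""
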