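"""Exception hierarchy shared across the package.

``ConfigError`` marks invalid configuration (CLI exit code 2),
``DataError`` marks unusable input data (CLI exit code 3).
"""


class DFCError(Exception):
    """Base class for all package errors."""


class ConfigError(DFCError):
    """A parameter or configuration value is invalid."""


class DataError(DFCError):
    """Input data cannot be parsed or does not satisfy a precondition."""
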