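"""Exception hierarchy shared across the package."""


class TristateError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(TristateError, ValueError):
    """A configuration value is invalid; the message names the field."""


class ParseError(TristateError, ValueError):
    """An input file could not be parsed; the message names the line."""


class ConsistencyError(TristateError, ValueError):
    """Cross-table references are inconsistent (e.g. unknown gene ids)."""


class ContractViolation(TristateError, ValueError):
    """An operation precondition was violated by the caller."""
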