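"""Exception hierarchy shared across the package."""


class FaerskitError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(FaerskitError):
    """Invalid simulation or run configuration (names the offending field)."""


class FormatError(FaerskitError):
    """Malformed input file (names the column or line where parsing failed)."""


class DictionaryError(FaerskitError):
    """Inconsistent PT->SOC dictionary (e.g. conflicting duplicate PTs)."""


class DomainError(FaerskitError):
    """Arguments outside the mathematical domain of an operation."""
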