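"""Exception hierarchy shared across the package."""


class BcgError(Exception):
    """Base class for all package errors."""


class DomainError(BcgError, ValueError):
    """A value lies outside the mathematical domain of an operation."""


class ConfigError(BcgError, ValueError):
    """Invalid filter/protocol/generator configuration."""


class InputError(BcgError, ValueError):
    """Input data violate a precondition (too short, inconsistent, ...)."""


class ParseError(BcgError, ValueError):
    """A file could not be parsed; the message names the offending row."""
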