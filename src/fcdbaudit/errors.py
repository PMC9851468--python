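"""Exception hierarchy shared across the package."""


class FCDBAuditError(Exception):
    """Base class for all package errors."""


class ParseError(FCDBAuditError):
    """A file could not be parsed; the message names the offending line."""


class UnitError(FCDBAuditError):
    """An unknown or unsupported unit string was encountered."""


class IntegrityError(FCDBAuditError):
    """Structural constraints violated (duplicate keys, broken invariants)."""


class ScopeError(FCDBAuditError, KeyError):
    """A requested food/database/component is absent from the panel."""


class DomainError(FCDBAuditError, ValueError):
    """An operation was called outside its mathematical domain."""


class ConfigError(FCDBAuditError, ValueError):
    """A generator or CLI configuration is invalid."""
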