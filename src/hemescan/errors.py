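"""Exception hierarchy shared across hemescan modules."""


class HemescanError(Exception):
    """Base class for all errors raised by hemescan."""


class FormatError(HemescanError):
    """Structurally malformed input (bad FASTA layout, bad pattern syntax)."""


class ValidationError(HemescanError):
    """Well-formed input that violates a domain constraint."""


class ContractError(HemescanError):
    """Caller violated an API precondition (e.g. mismatched window/class)."""


class ConfigError(HemescanError):
    """Invalid or unknown configuration key/value."""
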