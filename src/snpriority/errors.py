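"""Exception hierarchy shared across the package."""


class SnpriorityError(Exception):
    """Base class for all package-specific errors."""


class ParseError(SnpriorityError):
    """A field could not be parsed; carries the offending raw string."""

    def __init__(self, message: str, raw: str | None = None):
        super().__init__(message)
        self.raw = raw


class UnsupportedResidue(SnpriorityError):
    """An amino-acid code outside the 20 canonical residues (e.g. Ter, Xaa)."""


class ConfigurationError(SnpriorityError):
    """Fatal input-contract violation (missing column, empty table, ...)."""
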