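"""Exception hierarchy.

Every error raised by the package derives from :class:`CosymbioError` so
callers (and the CLI) can distinguish data problems from programming errors.
"""


class CosymbioError(Exception):
    """Base class for all package errors."""


class FormatError(CosymbioError):
    """A file is structurally not the format it claims to be (e.g. empty FASTA)."""


class ParseError(CosymbioError):
    """A line or token could not be parsed; carries file/line context in the message."""


class ValidationError(CosymbioError):
    """Parsed content violates a domain invariant (duplicate ids, bad coordinates...)."""


class UsageError(CosymbioError):
    """The caller asked for something incoherent (unknown dialect, overlapping groups...)."""


class EmptyInputError(CosymbioError):
    """An operation that needs at least one record received none."""
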