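"""Exception hierarchy for patchlift.

All errors raised by the library derive from :class:`PatchliftError` so that
callers (and the CLI) can catch everything with one except clause.
"""


class PatchliftError(Exception):
    """Base class for all patchlift errors."""


class SdiParseError(PatchliftError):
    """A variant file line could not be parsed; carries the line number."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


class IntegrityError(PatchliftError):
    """Internally inconsistent data (e.g. a delta column disagreeing with
    the alleles, or an offset map inconsistent with its sequences)."""


class ValidationError(PatchliftError):
    """Structurally invalid input (overlapping variants, unsorted records,
    invariant violations)."""


class ReferenceMismatchError(PatchliftError):
    """A record's reference allele disagrees with the reference sequence."""


class CoordinateError(PatchliftError):
    """A coordinate outside the addressable range of its chromosome."""
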