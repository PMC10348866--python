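"""Exception hierarchy for the pipeline.

Every error raised on bad user input derives from :class:`SangerBatchError`
so the CLI can map them onto exit codes (2 = empty input, 3 = format error).
"""


class SangerBatchError(Exception):
    """Base class for all package errors."""


class TraceFormatError(SangerBatchError):
    """Input blob is not a valid ABIF/AB1 file."""


class TraceTagError(SangerBatchError):
    """A required ABIF directory tag is missing."""


class TraceIntegrityError(SangerBatchError):
    """Per-base arrays (PBAS/PLOC/PCON) disagree in length."""


class ReferenceFormatError(SangerBatchError):
    """Reference file cannot be parsed in any supported format."""


class ArchiveError(SangerBatchError):
    """Zip archive of traces is corrupt."""


class EmptyInputError(SangerBatchError):
    """No usable traces were supplied."""
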