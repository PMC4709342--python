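"""Exception hierarchy for cysanchor.

Every error raised by the library derives from :class:`CysanchorError`, so
callers (and the CLI) can distinguish processing errors from bugs.
"""


class CysanchorError(Exception):
    """Base class for all cysanchor errors."""


class EmptyInputError(CysanchorError):
    """An input that must be non-empty was empty."""


class AlignmentShapeError(CysanchorError):
    """Sequences in an alignment do not all have the same length."""


class DuplicateIdError(CysanchorError):
    """Two records in one file share an identifier."""


class InvalidMetadataError(CysanchorError):
    """Barcode metadata violates its invariants."""


class MetadataParseError(CysanchorError):
    """A header's barcode-metadata block could not be parsed."""


class LengthMismatchError(CysanchorError):
    """Equal-length strings were required but not supplied."""


class UnknownResidueError(CysanchorError):
    """A residue is absent from a required lookup table."""


class InsufficientBarcodesError(CysanchorError):
    """The barcode pool ran out before all requests were satisfied."""


class ColumnRangeError(CysanchorError):
    """An alignment column index is out of range."""


class DuplicateColumnError(CysanchorError):
    """The same alignment column was requested twice."""


class MergeConflictError(CysanchorError):
    """The same homology class was mapped to two different barcodes."""


class MissingBarcodeError(CysanchorError):
    """A record's expected barcode is absent from its realigned sequence."""


class AmbiguousBarcodeError(CysanchorError):
    """A barcode occurs more than once in a realigned sequence."""


class NoMetadataError(CysanchorError):
    """A realigned record carries no barcode metadata."""


class ParameterError(CysanchorError):
    """A function parameter is outside its valid domain."""


class InputMismatchError(CysanchorError):
    """Two inputs that must describe the same sequences do not."""


class AdapterError(CysanchorError):
    """An external aligner invocation failed or produced invalid output."""
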