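"""Exception hierarchy for the soft-compression codec."""


class SoftCompError(Exception):
    """Base class for all errors raised by this package."""


class InputError(SoftCompError):
    """Unreadable or inconsistent user input (files, corpora)."""


class UnsupportedFormatError(InputError):
    """Input is readable but outside the supported pixel formats."""


class FormatError(SoftCompError):
    """Malformed serialized artifact: bad magic, bad CRC, truncation."""


class TruncationError(FormatError):
    """A bitstream ended in the middle of a codeword or field."""


class StructuralError(SoftCompError):
    """Shape/dimension mismatch between planes or components."""


class ValueRangeError(SoftCompError):
    """A pixel or symbol value lies outside its permitted range."""


class ParameterError(SoftCompError):
    """A tuning parameter violates its documented bounds."""


class ContractError(SoftCompError):
    """An internal precondition was violated by the caller."""


class CodebookMismatchError(SoftCompError):
    """Container was produced with a different codebook set."""
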