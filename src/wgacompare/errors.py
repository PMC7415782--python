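"""Exception hierarchy shared across the package."""


class WgaCompareError(Exception):
    """Base class for all package-specific errors."""


class FormatError(WgaCompareError):
    """Malformed input file (FASTA/GFF3/TSV) or inconsistent record structure."""


class ConsistencyError(WgaCompareError):
    """Internally inconsistent data (coordinates beyond chromosome ends, ...)."""


class ParameterError(WgaCompareError):
    """Invalid user-supplied parameter value."""


class CapacityError(WgaCompareError):
    """A randomized placement could not be satisfied within the retry budget."""


class EmptyInputError(WgaCompareError):
    """An operation received an empty data set it cannot work on."""


class NoPeakError(WgaCompareError):
    """No usable main peak in a k-mer depth histogram."""


class PreconditionError(WgaCompareError):
    """An operation's documented precondition was violated by the caller."""


class IntegrityError(WgaCompareError):
    """Bundled reference constants failed their checksum."""
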