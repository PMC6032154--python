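"""Exception hierarchy shared across the package."""


class GGapNBError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(GGapNBError, ValueError):
    """A function argument violates its contract."""


class FastaFormatError(GGapNBError):
    """Malformed FASTA input (bad header structure, duplicate ids, ...)."""


class DataError(GGapNBError):
    """Input data is structurally valid but unusable (e.g. an empty class)."""


class IntegrityError(GGapNBError):
    """A persisted model bundle is internally inconsistent."""
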