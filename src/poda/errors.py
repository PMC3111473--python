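"""Exception hierarchy shared across the package."""


class PodaError(Exception):
    """Base class for all package-specific errors."""


class FormatError(PodaError):
    """A file could not be parsed in the declared format."""


class ValidationError(PodaError):
    """An input violates a documented invariant (labels, ranges, counts)."""


class AlignmentError(PodaError):
    """Sample identifiers of two inputs cannot be reconciled."""
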