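"""Exception hierarchy shared across the package."""


class OwlAccelError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(OwlAccelError, ValueError):
    """A numeric parameter is outside its admissible range."""


class DataError(OwlAccelError, ValueError):
    """Input data are insufficient or malformed for the requested operation."""


class FrameError(DataError):
    """A codon-structured alignment whose length is not a multiple of three."""


class AlignmentTreeMismatchError(DataError):
    """Alignment taxa cannot be reconciled with the tree's tip set."""


class AnnotationError(DataError):
    """Gene annotation is inconsistent (e.g. TSS outside its chromosome)."""


class IncompletePosteriorError(DataError):
    """A branch posterior required by the ranking statistic is missing."""
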