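"""Exception types shared across the package."""


class TnfevolError(Exception):
    """Base class for all package-specific errors."""


class UnknownGeneError(TnfevolError, KeyError):
    """An event or query referenced a gene id absent from the genome state."""


class EventError(TnfevolError, ValueError):
    """An evolutionary event is malformed or cannot be applied."""


class ReplayError(TnfevolError):
    """Replaying an event script failed; message carries branch context."""


class TreeError(TnfevolError, ValueError):
    """A tree is missing required structure (rooting, labels, annotations)."""


class ReconstructionError(TnfevolError, ValueError):
    """A parsimony reconstruction cannot be computed as configured."""


class AnnotationError(TnfevolError, ValueError):
    """A functional annotation referenced an unknown gene or feature."""


class FormatError(TnfevolError, ValueError):
    """An input file violates the expected tabular or tree format."""
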