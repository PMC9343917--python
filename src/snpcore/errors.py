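"""Exception hierarchy shared across the package."""


class SnpcoreError(Exception):
    """Base class for all package-specific errors."""


class ParseError(SnpcoreError):
    """Malformed input file (carries a human-readable location when known)."""


class FormatError(SnpcoreError):
    """Structurally valid file that violates a required convention (e.g. no GT field)."""


class ValidationError(SnpcoreError):
    """Invalid argument or inconsistent in-memory object."""


class UndefinedValueError(SnpcoreError):
    """A statistic whose denominator is empty (all-missing column, no shared loci)."""


class ConstraintError(SnpcoreError):
    """A selection constraint (panel size, marker spacing) cannot be satisfied."""


class DegenerateInputError(SnpcoreError):
    """Input with no usable signal (e.g. a constant genotype matrix for PCA)."""


class PipelineError(SnpcoreError):
    """A pipeline stage failed; the message names the stage."""
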