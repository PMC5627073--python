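"""Exception hierarchy shared across the package."""


class ParsimetricsError(Exception):
    """Base class for all package-specific errors."""


class NexusParseError(ParsimetricsError):
    """A NEXUS or newick source could not be parsed."""


class MatrixValidationError(ParsimetricsError):
    """A character matrix violates a structural invariant."""


class PartitionError(ParsimetricsError):
    """A character partition is not total, not disjoint, or out of range."""


class TreeError(ParsimetricsError):
    """A tree violates a structural invariant or does not match its matrix."""


class SearchError(ParsimetricsError):
    """A tree search cannot be run as configured."""
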