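"""Exception hierarchy shared across the package."""


class RatpopgenError(Exception):
    """Base class for all package-specific errors."""


class InputError(RatpopgenError):
    """Unreadable, empty, or malformed input file."""


class AlignmentLengthError(RatpopgenError):
    """Sequences in one locus alignment do not share a common aligned length."""


class MetadataError(RatpopgenError):
    """Locus metadata inconsistent with the sequence data (e.g. unknown population)."""


class CoordinateError(RatpopgenError):
    """Aligned coordinate out of range."""


class EmptyCountsError(RatpopgenError):
    """No complete codon available for site-class counting."""


class InsufficientSampleError(RatpopgenError):
    """Fewer than two alleles available for a diversity statistic."""


class AggregationError(RatpopgenError):
    """Per-locus statistics cannot be pooled (mixed site classes or populations)."""


class ModelError(RatpopgenError):
    """Invalid demographic model parameters."""


class ExportError(RatpopgenError):
    """No eligible data for a requested export."""
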