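"""Exception hierarchy for reciprome."""


class ReciromeError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(ReciromeError):
    """Invalid study design, effect table, thresholds or config file."""


class NormalizationError(ReciromeError):
    """Count normalization cannot proceed (e.g. a sample with no usable
    positive-control counts)."""


class EnrichmentError(ReciromeError):
    """Gene-set enrichment cannot be computed (disjoint set, degenerate null)."""
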