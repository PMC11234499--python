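"""Exception hierarchy for oxystrat.

Every failure mode the pipeline can hit on real inputs gets its own class so
callers can distinguish, e.g., a degenerate score distribution from a Cox fit
that failed to converge.
"""


class OxystratError(Exception):
    """Base class for all oxystrat-specific errors."""


class SignatureOverlapError(OxystratError):
    """No signature gene is present in the expression matrix."""


class DegenerateScoresError(OxystratError):
    """Score distribution is constant; quantile strata are undefined."""


class NoEvaluableCutoffsError(OxystratError):
    """Every percentile in a cutoff sweep was guarded out or degenerate."""


class RankDeficiencyError(OxystratError):
    """Cox design matrix is not full rank (e.g. a constant covariate)."""


class ConvergenceError(OxystratError):
    """Cox partial-likelihood maximization failed to converge
    (typically monotone likelihood from complete separation)."""


class EmptyResultError(OxystratError):
    """A screen or comparison produced no testable rows."""


class AlignmentError(OxystratError):
    """Sample identifiers cannot be aligned across data sources."""


class DuplicateIdError(OxystratError):
    """Duplicate gene/taxon/sample identifiers where uniqueness is required."""


class MalformedInputError(OxystratError):
    """An input file violates the expected layout or value domain."""


class PipelineError(OxystratError):
    """A pipeline stage failed; the message names the stage and the cause."""
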