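"""Exception hierarchy.

All package-specific failures derive from :class:`SfindexError` so callers
can catch one base class at pipeline boundaries. Names follow the failure
mode, not the module that raises them.
"""


class SfindexError(Exception):
    """Base class for all sfindex errors."""


class CurveUnderdeterminedError(SfindexError):
    """Standard-curve fit attempted with fewer than three distinct dilutions."""


class DegenerateCurveError(SfindexError):
    """Standard-curve slope is zero or positive (inverted/corrupt dilution series)."""


class QcFailedError(SfindexError):
    """Amplification efficiency outside the acceptance window; run must be repeated."""


class InvalidSampleError(SfindexError):
    """Sample cannot be normalized (housekeeping gene did not amplify)."""


class IncompleteExpressionError(SfindexError):
    """A target gene is missing from the normalized-expression mapping."""


class UndefinedRocError(SfindexError):
    """ROC threshold derivation requested with a single-class label vector."""


class DegenerateFeatureError(SfindexError):
    """A feature column has zero variance and cannot be z-scored."""


class PerfectSeparationError(SfindexError):
    """Unpenalized logistic fit diverged on (quasi-)separable data."""


class EmptyBandError(SfindexError):
    """Threshold search band excludes every candidate threshold."""


class StratificationError(SfindexError):
    """A class is too small for the requested stratified split or CV folds."""


class AlignmentError(SfindexError):
    """Paired inputs (categories vs tiers, features vs labels) differ in length."""


class ConfigError(SfindexError):
    """Inconsistent simulator or pipeline configuration."""


class PipelineError(SfindexError):
    """Too many per-sample failures for the cohort run to be trusted."""
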