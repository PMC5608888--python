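"""Exception hierarchy.

Every error the library raises deliberately derives from :class:`NetlieError`,
so callers (and the CLI) can distinguish usage errors from bugs.
"""


class NetlieError(Exception):
    """Base class for all errors raised by netlie."""


class InvalidParameterError(NetlieError, ValueError):
    """A parameter is outside its documented domain."""


class TooShortSegmentError(NetlieError):
    """A time-series segment is shorter than the configured minimum."""


class WrongSubjectTypeError(NetlieError):
    """An operation meant for liars was applied to a lie-free log (or vice versa)."""


class ZeroVarianceError(NetlieError):
    """A channel or variable has no variance, so a correlation/test is undefined."""


class DegenerateThresholdError(NetlieError):
    """Sparsity threshold so low that the binarized graph would have no edges."""


class UndefinedPathError(NetlieError):
    """Characteristic path length requested for a graph with no edges."""


class DegenerateNullError(NetlieError):
    """Random-reference ensemble has zero mean clustering or path length."""


class NoValidRangeError(NetlieError):
    """Sparsity-range selection produced an empty range."""


class DegenerateModelError(NetlieError):
    """A statistical model is degenerate (e.g. zero residual variance with nonzero effect)."""


class RankDeficiencyError(NetlieError):
    """Design matrix is rank deficient (collinear covariates/predictors)."""


class ConfigError(NetlieError):
    """Study configuration file is invalid."""


class DataError(NetlieError):
    """Input data directory or cohort is unusable."""
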