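"""Exception hierarchy for riverfce.

Exit-code mapping used by the CLI: validation errors (2), consistency
failures (3), numerical/degenerate-data failures (4).
"""


class RiverFCEError(Exception):
    """Base class for all riverfce errors."""


class SystemValidationError(RiverFCEError):
    """Indicator-system config is malformed (missing indicator, overlapping
    or gapped grade intervals, dangling parent reference)."""


class DomainError(RiverFCEError):
    """An observed value lies outside the union of an indicator's grades."""


class MatrixValidationError(RiverFCEError):
    """A pairwise judgment matrix violates positivity/reciprocity, or a
    data matrix violates its structural contract."""


class ConsistencyError(RiverFCEError):
    """A judgment matrix failed the consistency-ratio test (CR >= 0.1)."""


class UnsupportedOrderError(RiverFCEError):
    """Judgment-matrix order outside the random-index table (n > 15)."""


class DegenerateDataError(RiverFCEError):
    """Data carry no usable information (e.g. every column constant, or a
    single evaluation unit where entropy is undefined)."""


class NumericalError(RiverFCEError):
    """An iterative numerical procedure failed to converge."""
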