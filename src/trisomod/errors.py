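"""Exception hierarchy shared across the package."""


class TrisomodError(Exception):
    """Base class for all package-specific errors."""


class InvalidConfigError(TrisomodError, ValueError):
    """A configuration object or parameter is out of its valid range."""


class InvalidInputError(TrisomodError, ValueError):
    """An input table or vector violates a documented precondition."""


class GeneAlignmentError(TrisomodError, ValueError):
    """Gene identifiers of two inputs cannot be brought into correspondence."""


class DegenerateDataError(TrisomodError, ValueError):
    """The data admit no meaningful statistic (constant scores, empty group, ...)."""


class UndefinedMetricError(TrisomodError, ValueError):
    """A classification metric is undefined for the given labels."""


class DecompositionError(TrisomodError, ValueError):
    """A matrix factorization (e.g. Cholesky of a covariance) failed."""
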