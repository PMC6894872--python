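"""Package exception hierarchy."""


class MvextrapError(Exception):
    """Base class for all package errors."""


class SingularDesignError(MvextrapError):
    """Design matrix is rank deficient (offending columns named in the message)."""


class SingularCovarianceError(MvextrapError):
    """A covariance (block) that must be inverted is numerically singular."""


class DimensionError(MvextrapError):
    """Shapes or index sets do not line up."""


class DataError(MvextrapError):
    """Input data violate a precondition (missingness, alignment, parsing)."""
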