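"""Exception hierarchy for logica.

All errors raised by the library derive from :class:`LogicaError` so that
callers (and the genome scan, which must never abort on a single region)
can catch them uniformly.
"""


class LogicaError(Exception):
    """Base class for all logica errors."""


class InvalidLDError(LogicaError):
    """LD matrix is not a valid SNP-SNP correlation matrix."""


class DegenerateLDError(InvalidLDError):
    """LD matrix has no positive eigenvalue."""


class DimensionError(LogicaError):
    """Vector/matrix dimensions do not match."""


class BoundaryLikelihoodError(LogicaError):
    """Joint covariance not positive definite (usually |rho_g| at the PSD
    boundary combined with mismatched eigenbasis truncation)."""


class InsufficientRankError(LogicaError):
    """Retained LD rank too small for the requested operation."""


class InternalConsistencyError(LogicaError):
    """An algorithmic invariant (e.g. EM monotonicity) was violated; a bug trap."""


class FormatError(LogicaError):
    """Malformed input file."""


class ValidationError(LogicaError):
    """Input violates a documented invariant (overlapping blocks, duplicate
    SNP ids, zero-variance genotype column, ...)."""


class InsufficientRegionsError(LogicaError):
    """Too few regions for a genome-wide quantity (null-proportion estimation)."""
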