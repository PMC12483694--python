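"""Exception hierarchy shared across the package."""


class SisquocError(Exception):
    """Base class for all package-specific errors."""


class InvalidMarginError(SisquocError):
    """A margin vector is malformed (negative entry or not summing to 1)."""


class InfeasiblePartialTableError(SisquocError):
    """A partially filled table admits no completion (upper < lower bound)."""


class InfeasibleMomentsError(SisquocError):
    """A moment vector violates its Frechet feasibility constraints."""


class DimensionError(SisquocError):
    """An operation received a table of unsupported shape."""


class InconsistentMarginsError(SisquocError):
    """Bivariate tables imply conflicting univariate margins."""


class FileFormatError(SisquocError):
    """A structured-text file failed to parse or violated an invariant."""
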