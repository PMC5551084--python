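"""Exception hierarchy for reefrugosity.

All errors derive from :class:`ReefRugosityError` so callers can catch the
package's failures with one clause; each also derives from the closest
built-in (ValueError) so generic handling keeps working.
"""


class ReefRugosityError(ValueError):
    """Base class for all package-specific errors."""


class EmptySurfaceError(ReefRugosityError):
    """A surface with no usable geometry (e.g. an all-masked heightfield)."""


class DegenerateGeometryError(ReefRugosityError):
    """Geometry too degenerate for the requested fit (collinear vertices, zero range)."""


class InvalidTransformError(ReefRugosityError):
    """A rigid transform whose rotation is not special-orthogonal."""


class MeshFormatError(ReefRugosityError):
    """A mesh file that cannot be parsed, or uses an unsupported dialect."""


class ParameterError(ReefRugosityError):
    """An argument outside its valid domain (negative sizes, unknown labels...)."""


class InsufficientReplicationError(ReefRugosityError):
    """Fewer repeated measurements than the estimator requires."""


class AlignmentError(ReefRugosityError):
    """Inputs that should share index structure (quadrats, pairs) do not."""


class MissingDataError(ReefRugosityError):
    """A requested region or group has no data."""


class UndefinedStatisticError(ReefRugosityError):
    """A statistic that is undefined for the given input (zero variance, zero range)."""


class CollinearityError(ReefRugosityError):
    """A rank-deficient regression design."""
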