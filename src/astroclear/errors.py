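"""Exception hierarchy shared across the package.

All domain/model violations derive from :class:`DomainError` (a ``ValueError``)
so callers may catch either; structural problems with input tables or images
raise :class:`SchemaError`.  The CLI maps these onto exit codes 3 and 2.
"""


class AstroclearError(Exception):
    """Base class for all package-specific errors."""


class DomainError(AstroclearError, ValueError):
    """A parameter is outside the model's mathematical domain."""


class InvalidRegimeError(DomainError):
    """The implied per-day loss fraction d = D*24/V is >= 1: the trajectory
    would hit zero within a day and the geometric model does not apply."""


class NoDeclineError(DomainError):
    """N_T >= S: there is no decline to explain, so V is undefined."""


class NoDeathError(DomainError):
    """D = 0 with a declining population: no finite V can reconcile them."""


class InsufficientDataError(AstroclearError):
    """Too few samples/snapshots/polygons to compute the requested quantity."""


class PlacementError(AstroclearError):
    """A sampling field does not fit inside the tissue at the requested spot."""


class PackingInfeasibleError(AstroclearError):
    """Dart-throwing could not place the requested number of points."""


class GenerationError(AstroclearError):
    """A synthetic scene could not be built under the requested constraints."""


class SchemaError(AstroclearError):
    """An input table or image does not match the declared schema."""


class DegenerateInputError(DomainError):
    """Input is constant/empty in a way that leaves the statistic undefined
    (all-zero series, constant image, zero cells in a field)."""
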