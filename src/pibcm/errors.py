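"""Exception hierarchy shared across the package."""


class PibcmError(Exception):
    """Base class for all package-specific errors."""


class DomainError(PibcmError, ValueError):
    """An input value lies outside the physically/mathematically valid domain."""


class InsufficientDataError(PibcmError, ValueError):
    """Too few observations to perform the requested fit."""


class DegenerateDesignError(PibcmError, ValueError):
    """The design matrix is singular (e.g. a single distinct temperature,
    or collinear spline nodes)."""


class GeometryError(PibcmError, ValueError):
    """Grids or maps that must share geometry (coordinates, masks, month
    count) do not."""


class OrderingError(PibcmError, ValueError):
    """A (min, max) pair was supplied out of order."""
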