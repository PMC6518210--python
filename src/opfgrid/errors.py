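"""Exception hierarchy for opfgrid.

All package-specific failures derive from :class:`OpfgridError` so callers
(and the CLI) can catch one base class.
"""


class OpfgridError(Exception):
    """Base class for all opfgrid errors."""


class InvalidDomainError(OpfgridError, ValueError):
    """A domain box or reference interval is degenerate (lo >= hi)."""


class InvalidOrderError(OpfgridError, ValueError):
    """A polynomial order is negative or otherwise unusable."""


class UnderdeterminedFitError(OpfgridError, ValueError):
    """Fewer observations than polynomial coefficients requested."""


class DuplicateStationError(OpfgridError, ValueError):
    """Two stations share the exact same (lon, lat) coordinates."""


class SchemaError(OpfgridError, ValueError):
    """An input table is missing required columns."""


class EmptyInputError(OpfgridError, ValueError):
    """No usable observations remain after parsing."""


class InvalidRadiusError(OpfgridError, ValueError):
    """A Cressman influence radius is non-positive."""


class InvalidLagError(OpfgridError, ValueError):
    """A semivariogram lag distance is negative."""


class NoNeighborsError(OpfgridError, RuntimeError):
    """The adaptive influence radius hit its cap before finding enough
    neighbours for some query point."""


class SingularKrigingError(OpfgridError, RuntimeError):
    """The ordinary-kriging system is singular (e.g. duplicate points)."""


class ConfigError(OpfgridError, ValueError):
    """A configuration file contains unknown or ill-typed keys."""
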