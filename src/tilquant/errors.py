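"""Exception hierarchy for tilquant.

Validation failures raise :class:`TilquantError` subclasses so that the CLI
can distinguish user/data errors (exit code 2) from internal bugs (exit 1).
"""


class TilquantError(Exception):
    """Base class for all tilquant errors."""


class ParameterError(TilquantError, ValueError):
    """A configuration or specification field is invalid."""


class GeometryError(TilquantError, ValueError):
    """A polygon is degenerate, self-intersecting or out of frame."""


class CapacityError(TilquantError, RuntimeError):
    """Rejection placement could not fit the requested number of objects."""


class PlacementError(TilquantError, RuntimeError):
    """An artifact or cell could not be placed under the overlap policy."""


class SchemaError(TilquantError, ValueError):
    """A CSV/GeoJSON file does not match the expected schema."""


class DataError(TilquantError, ValueError):
    """Input values violate a data invariant (negative density, NaN, ...)."""


class ZeroAreaError(TilquantError, ValueError):
    """A region has zero area; a density cannot be computed."""


class JoinError(TilquantError, ValueError):
    """Patient identifiers do not align between input tables."""
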