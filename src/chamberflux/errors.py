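"""Exception types used across the package."""


class ChamberFluxError(Exception):
    """Base class for package errors."""


class InvalidConfigError(ChamberFluxError, ValueError):
    """A configuration object violates its invariants."""


class InvalidGeometryError(ChamberFluxError, ValueError):
    """Chamber geometry (area, volume) is non-physical."""


class InsufficientDataError(ChamberFluxError, ValueError):
    """Too few samples/points for the requested operation."""


class SchemaError(ChamberFluxError, ValueError):
    """A CSV file is missing required columns or has malformed values."""


class UndefinedStatisticError(ChamberFluxError, ValueError):
    """A statistic is undefined for the given input (e.g. sd of one value)."""
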