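"""Exception hierarchy for gridspac.

All package-specific failures derive from :class:`GridspacError` so callers
can catch one base class; validation failures carry enough context (cell ids,
dates, config key paths) to locate the offending input.
"""


class GridspacError(Exception):
    """Base class for all gridspac errors."""


# --- grid_domain ---------------------------------------------------------

class RoutingError(GridspacError):
    """Base class for invalid routing graphs."""


class TwoUpstreamError(RoutingError):
    """A cell would receive more than one upstream contributor."""


class CycleError(RoutingError):
    """The direction map contains a closed loop."""


class DanglingError(RoutingError):
    """A drainage chain leaves the grid other than at the outlet."""


class ShapeError(GridspacError):
    """An array input has an unusable shape."""


# --- soil_params ---------------------------------------------------------

class EmptySampleError(GridspacError):
    """No soil samples supplied."""


class TextureError(GridspacError):
    """Sand/silt/clay fractions are invalid (wrong sum or out of range)."""


class ThicknessError(GridspacError):
    """A soil layer thickness is non-positive."""


# --- process_core / routing_engine ---------------------------------------

class ConvergenceError(GridspacError):
    """The soil-water solver failed to converge at the minimum sub-step."""


class UnknownEventError(GridspacError):
    """A management event type is not recognised."""


class CoverageError(GridspacError):
    """Gridded output does not cover all routed cells."""


class YearRangeError(GridspacError):
    """Requested years are outside the simulated period."""


# --- evaluation ----------------------------------------------------------

class NonMonotonicTimeError(GridspacError):
    """Timestamps are not strictly increasing."""


class LengthMismatchError(GridspacError):
    """Measured and simulated series have different lengths."""


class InsufficientDataError(GridspacError):
    """Too few valid pairs to compute the requested statistic."""


# --- cli_io --------------------------------------------------------------

class ConfigError(GridspacError):
    """Invalid run configuration; message names the key path."""


class SchemaError(GridspacError):
    """An input table does not match its expected schema."""


class DateGapError(GridspacError):
    """The weather series is missing one or more calendar days."""


class ParamError(GridspacError):
    """Invalid generator parameters."""
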