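"""Exception hierarchy.

Every error raised by the library derives from :class:`AxiscopeError`, so
callers (and the CLI) can distinguish domain failures from programming bugs.
Each CLI error class maps to a distinct nonzero exit code via ``exit_code``.
"""


class AxiscopeError(Exception):
    """Base class for all axiscope domain errors."""

    exit_code = 1


# --- geometry_axis ---------------------------------------------------------

class EmptyRegion(AxiscopeError):
    """Dorsal or ventral annotation set is empty; the axis is undefined."""

    exit_code = 10


class DegenerateAxis(AxiscopeError):
    """The mean dorsal-to-ventral difference vector has zero length."""

    exit_code = 11


class ConstantProjection(AxiscopeError):
    """All spots project to one point; min-max scaling is undefined."""

    exit_code = 12


# --- profiling -------------------------------------------------------------

class InvalidBinCount(AxiscopeError):
    exit_code = 20


class OutOfRange(AxiscopeError):
    """A scaled axis position falls outside [0, 1]."""

    exit_code = 21


class NoSpots(AxiscopeError):
    """No spot carries a defined feature value after filtering."""

    exit_code = 22


class TooFewBins(AxiscopeError):
    """Fewer non-empty bins than the loess degree requires."""

    exit_code = 23


class EmptyModule(AxiscopeError):
    """No gene of the module is present in the matrix."""

    exit_code = 24


# --- qc --------------------------------------------------------------------

class EmptyResult(AxiscopeError):
    """QC removed every observation or every gene."""

    exit_code = 30


class MissingAnnotations(AxiscopeError):
    """Biotype enrichment requested without gene annotations."""

    exit_code = 31


# --- colocalization --------------------------------------------------------

class DegenerateInput(AxiscopeError):
    """Too few spots or too few variable cell types to correlate."""

    exit_code = 40


# --- synthetic_data --------------------------------------------------------

class InvalidFraction(AxiscopeError):
    exit_code = 50


class TooFewSpots(AxiscopeError):
    exit_code = 51


class InvalidSpec(AxiscopeError):
    """Negative baseline mean or dispersion in a gene spec."""

    exit_code = 52


class InvalidConcentration(AxiscopeError):
    exit_code = 53


# --- io_cli ----------------------------------------------------------------

class MissingColumn(AxiscopeError):
    exit_code = 60


class DuplicateSpotId(AxiscopeError):
    exit_code = 61


class NonNumericCoordinate(AxiscopeError):
    exit_code = 62


class DimensionMismatch(AxiscopeError):
    exit_code = 63


class NegativeCount(AxiscopeError):
    exit_code = 64


class ConfigError(AxiscopeError):
    exit_code = 65
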