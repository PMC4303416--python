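"""Exception hierarchy.

All toolkit exceptions derive from :class:`EdrsError` so callers can catch
one base class at pipeline boundaries.
"""


class EdrsError(Exception):
    """Base class for all errors raised by this package."""


class SchemaError(EdrsError):
    """A required column could not be resolved in an input file."""


class FormatError(EdrsError):
    """The file is structurally invalid (e.g. non-uniform time grid)."""


class DataError(EdrsError):
    """Values are unparseable or non-finite."""


class ParameterError(EdrsError):
    """A parameter violates its contract (sign, range, consistency)."""


class SegmentationError(EdrsError):
    """A breath window is degenerate or cannot be processed."""


class DegenerateBreathError(EdrsError):
    """A breath has too little usable volume/signal for elastance estimation."""


class ConsistencyError(EdrsError):
    """Objects that must agree (grids, patients, modes) do not."""


class InsufficientDataError(EdrsError):
    """A computation requires valid samples that are missing."""


class SampleSizeError(EdrsError):
    """Too few breaths for a statistical comparison."""


class SimulationError(EdrsError):
    """The forward simulation entered a non-physical state."""
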